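"""Run the embedded GA wrapper and watch it recover a planted feature subset.

The GA minimizes FF = 1/ACC_train + a*(m/d) + b/width over binary feature
masks, evaluating each candidate by training a linear SVM on the training
split only.  With balanced weights the optimum is the planted informative
block: accurate, small, and wide-margin.
"""

import svmga

cohort = svmga.generate_cohort(
    svmga.GeneratorConfig(n_samples=56, n_features=60, n_positive=32,
                          n_informative=5, effect_size=6.0, seed=1)
)
split = svmga.stratified_split(cohort, seed=1)

config = svmga.GAConfig(n_chromosomes=200, max_generations=150, seed=1,
                        selection="rank", a=1.0, b=1.0)
result = svmga.run_ga(split, config)

print("epoch  best_ff  train  test  m")
for rec in result.trajectory[:: max(1, len(result.trajectory) // 10)]:
    print(f"{rec.epoch:5d}  {rec.best_ff:7.4f}  {rec.train_acc:.3f} {rec.test_acc:.3f} "
          f"{rec.m_best:3d}")

planted = set(cohort.informative_indices.tolist())
selected = set(result.best_subset.indices.tolist())
jaccard = len(planted & selected) / len(planted | selected)
print(f"\ndimensionality reduced {cohort.n_features} -> {result.best_subset.m}")
print(f"selected columns: {sorted(selected)} (planted: {sorted(planted)}, "
      f"Jaccard overlap {jaccard:.2f})")
print(f"final fitness {result.best_fitness.ff_total:.4f} = "
      f"1/acc {result.best_fitness.ff1:.4f} + cardinality {result.best_fitness.ff2:.4f} "
      f"+ margin {result.best_fitness.ff3:.4f}")
print(f"held-out test accuracy: {result.trajectory[-1].test_acc:.3f}")
# The best-fitness curve is monotone (elitism); dimensionality m shrinks as
# the search trades nuisance features for a wider margin on fewer columns.
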