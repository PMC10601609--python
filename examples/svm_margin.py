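"""Train a linear SVM in dual form and inspect its margin geometry.

The decision boundary w = sum_i alpha_i y_i x_i comes from the dual
solution; the geometric margin width is 2 / ||w||_2, the distance between
the two supporting hyperplanes.  This width is the quantity the GA's
margin term rewards.
"""

import numpy as np

import svmga

# two opposite points: the maximum-margin plane sits midway, width = distance
toy = svmga.train_linear_svm(np.array([[3.0], [-3.0]]), np.array([1, -1]), C=1e6)
print(f"two points at x=+-3: w={toy.w[0]:.4f}, bias={toy.bias:.4f}, "
      f"margin width={svmga.margin_width(toy):.4f} (equals the 6.0 inter-point distance)")

rng = np.random.default_rng(7)
X = np.vstack([rng.normal([2.5, 2.0], 0.5, (10, 2)), rng.normal([-2.0, -2.5], 0.5, (10, 2))])
y = np.array([1] * 10 + [-1] * 10)
model = svmga.train_linear_svm(X, y, C=1e6)
print(f"\n2-D separable set (n=20): {len(model.support_indices)} support vectors, "
      f"w={np.round(model.w, 4)}, margin width={svmga.margin_width(model):.4f}")
print(f"dual feasibility: sum(alpha_i y_i) = {np.sum(model.alphas * y):.2e} "
      f"(zero within tolerance)")
# Only the support vectors (nonzero alpha) determine the boundary; the
# margin width measures how far apart the classes sit along w.
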