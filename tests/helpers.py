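"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: a grid/refinement
search for the 2-D maximum-margin hyperplane, a joint-frequency-table
mutual information, and exhaustive feature-subset enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def grid_max_margin(X: np.ndarray, y: np.ndarray, n_coarse: int = 20000, refine: int = 2000):
    """Brute-force maximum-margin separator for separable 2-D data.

    Scans hyperplane normal directions u(theta) on a fine angular grid and
    maximizes the worst-case signed functional margin
    (min over +: u.x) - (max over -: u.x), then refines locally.  Returns
    (width, unit_normal) where width is twice the best half-margin.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)

    def half_margin(theta: float) -> float:
        u = np.array([math.cos(theta), math.sin(theta)])
        proj = X @ u
        return (proj[y > 0].min() - proj[y < 0].max()) / 2.0

    thetas = np.linspace(0.0, 2.0 * math.pi, n_coarse, endpoint=False)
    margins = np.array([half_margin(t) for t in thetas])
    best = int(np.argmax(margins))
    lo = thetas[best] - 2.0 * math.pi / n_coarse
    hi = thetas[best] + 2.0 * math.pi / n_coarse
    fine = np.linspace(lo, hi, refine)
    fm = np.array([half_margin(t) for t in fine])
    t_star = fine[int(np.argmax(fm))]
    u = np.array([math.cos(t_star), math.sin(t_star)])
    return 2.0 * fm.max(), u


def contingency_mi_bits(x_discrete: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI from an explicitly accumulated joint frequency table."""
    table: dict[tuple, int] = {}
    for xv, yv in zip(x_discrete, y):
        table[(xv, yv)] = table.get((xv, yv), 0) + 1
    n = len(y)
    px: dict = {}
    py: dict = {}
    for (xv, yv), c in table.items():
        px[xv] = px.get(xv, 0) + c
        py[yv] = py.get(yv, 0) + c
    mi = 0.0
    for (xv, yv), c in table.items():
        p = c / n
        mi += p * math.log2(p / ((px[xv] / n) * (py[yv] / n)))
    return mi


def entropy_bits(counts) -> float:
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c > 0)


def enumerate_best_subset(X_train, y_train, config):
    """Exhaustively score every non-empty subset; return (best_mask, best_ff)."""
    from svmga.ga import FeatureSubset, evaluate_fitness

    d = X_train.shape[1]
    best_ff = math.inf
    best_mask = None
    for bits in itertools.product([False, True], repeat=d):
        mask = np.array(bits)
        if not mask.any():
            continue
        bd = evaluate_fitness(FeatureSubset(mask), X_train, y_train, config)
        ff = bd.ff_total if math.isfinite(bd.ff_total) else math.inf
        if ff < best_ff:
            best_ff = ff
            best_mask = mask
    return best_mask, best_ff
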