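"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: rank-test p-values by
full enumeration, and registration optima by exhaustive coarse-to-fine
grid search over the six-parameter space.
"""

from itertools import combinations, product

import numpy as np

from ctmotion.registration import (
    RigidTransform,
    correlation_metric,
    params_to_matrix,
)


def mann_whitney_exact_p(a, b, alternative="two-sided"):
    """Exact Mann-Whitney p by enumerating all rank assignments (no ties)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    all_u = np.array(
        [
            np.sum(ranks[list(pick)]) - n_a * (n_a + 1) / 2
            for pick in combinations(range(len(pooled)), n_a)
        ]
    )
    if alternative == "two-sided":
        mean_u = len(a) * len(b) / 2
        return float(np.mean(np.abs(all_u - mean_u) >= abs(u_obs - mean_u) - 1e-12))
    if alternative == "greater":
        return float(np.mean(all_u >= u_obs - 1e-12))
    return float(np.mean(all_u <= u_obs + 1e-12))


def wilcoxon_exact_p(d, alternative="two-sided"):
    """Exact Wilcoxon signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, float)
    d = d[d != 0]
    mags = np.abs(d)
    assert len(np.unique(mags)) == len(mags), "oracle assumes no tied magnitudes"
    ranks = np.argsort(np.argsort(mags)) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    all_w = np.array([np.sum(ranks[list(signs)]) for k in range(n + 1) for signs in combinations(range(n), k)])
    if alternative == "two-sided":
        mean_w = n * (n + 1) / 4
        return float(np.mean(np.abs(all_w - mean_w) >= abs(w_obs - mean_w) - 1e-12))
    if alternative == "greater":
        return float(np.mean(all_w >= w_obs - 1e-12))
    return float(np.mean(all_w <= w_obs + 1e-12))


def grid_search_register(contour, target, box_mm=2.0, box_deg=2.0, final_step=0.1):
    """Coarse-to-fine exhaustive search of the 6-parameter space.

    Uses the same centred parameterisation as the Nelder-Mead path (rotation
    about the contour centroid) so optima are directly comparable. Returns
    the best RigidTransform at ``final_step`` resolution.
    """
    center = contour.sample_points.mean(axis=0)

    def build(p):
        base = params_to_matrix(p)
        R = base.rotation
        return RigidTransform.from_rotation_translation(
            R, base.translation_vector + center - R @ center
        )

    def value(p):
        try:
            return correlation_metric(contour, target, build(p))
        except ValueError:
            return -np.inf

    best = np.zeros(6)
    # stage 1: full box at 1 mm / 1 deg
    offsets = np.arange(-box_mm, box_mm + 1e-9, 1.0)
    grid = [np.array(c, float) for c in product(*[offsets] * 6)]
    best = max(grid, key=value)
    # refinement stages around the incumbent
    for step in (0.5, 0.25):
        offs = np.array([-step, 0.0, step])
        grid = [best + np.array(c) for c in product(*[offs] * 6)]
        best = max(grid, key=value)
    offs = final_step * np.array([-2, -1, 0, 1, 2])
    grid = [best + np.array(c) for c in product(*[offs] * 6)]
    best = max(grid, key=value)
    return build(best), best
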