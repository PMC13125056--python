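"""Resampling statistics for time courses and layer curves.

Contains the sign-permutation test against chance, the condition-swap
permutation test for group differences, Benjamini-Hochberg FDR adjustment,
percentile bootstrap CIs for means / peak locations / peak differences, and
the brain-network hierarchy correlation (Spearman with an exhaustive
permutation p-value, 7! = 5040 orderings for seven features).

Rank p-values use (1 + #{|null| >= |observed|}) / (1 + n_perm), which counts
the observed statistic into its own null set and is therefore always > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream

__all__ = [
    "TimecoursePvalues",
    "PeakEstimate",
    "HierarchyCorrelation",
    "sign_permutation_test",
    "condition_swap_test",
    "fdr_bh",
    "bootstrap_ci_mean",
    "peak_location",
    "bootstrap_peak_ci",
    "bootstrap_peak_difference",
    "hierarchy_correlation",
]


@dataclass
class TimecoursePvalues:
    """Raw and FDR-adjusted p-values per timepoint (or layer)."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray  # boolean mask at alpha
    alpha: float
    n_perm: int
    tail: str = "two-sided"


@dataclass
class PeakEstimate:
    """Peak location on the measurement grid with a bootstrap 95% CI."""

    peak: float
    ci: tuple[float, float]
    n_boot: int
    tie_rule: str = "earliest"


@dataclass
class HierarchyCorrelation:
    """Spearman alignment between two processing hierarchies."""

    r_s: float
    p_value: float
    n_features: int
    n_permutations: int
    exhaustive: bool
    tail: str = "greater"


def _rank_p(null_abs: np.ndarray, obs_abs: np.ndarray) -> np.ndarray:
    """(1 + #{null >= obs}) / (1 + n) along the permutation axis (axis 0)."""
    n = null_abs.shape[0]
    return (1 + (null_abs >= obs_abs[None]).sum(axis=0)) / (1 + n)


def sign_permutation_test(
    subject_values: np.ndarray,
    n_perm: int = 10000,
    chance: float = 0.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> TimecoursePvalues:
    """Two-tailed sign-permutation test of the subject mean against chance.

    ``subject_values`` is (n_subjects, n_points); per permutation every
    subject's chance-centered values are multiplied by a random +-1 and the
    group mean recomputed.
    """
    vals = np.atleast_2d(np.asarray(subject_values, dtype=float)) - chance
    n_sub, n_points = vals.shape
    if n_sub < 2:
        raise ValueError("sign-permutation test needs at least 2 subjects")
    rng = substream(seed, "sign-permutation")
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    null = np.abs(signs @ vals) / n_sub  # (n_perm, n_points)
    obs = np.abs(vals.mean(axis=0))
    p_raw = _rank_p(null, obs)
    p_adj, mask = fdr_bh(p_raw, alpha)
    return TimecoursePvalues(
        p_raw=p_raw, p_adjusted=p_adj, significant=mask, alpha=alpha, n_perm=n_perm
    )


def condition_swap_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> TimecoursePvalues:
    """Two-tailed permutation test of a between-group mean difference.

    Subjects are pooled and randomly reassigned to groups of the original
    sizes; the statistic is the difference of group means per point.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both groups must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same points axis")
    pooled = np.vstack([a, b])
    n_a = a.shape[0]
    n = pooled.shape[0]
    rng = substream(seed, "condition-swap")
    obs = np.abs(a.mean(axis=0) - b.mean(axis=0))
    # all permutations at once: random sort keys give uniform reassignments
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    grand_sum = pooled.sum(axis=0)
    sums_a = pooled[perms[:, :n_a]].sum(axis=1)  # (n_perm, n_points)
    null = np.abs(sums_a / n_a - (grand_sum - sums_a) / (n - n_a))
    p_raw = _rank_p(null, obs)
    p_adj, mask = fdr_bh(p_raw, alpha)
    return TimecoursePvalues(
        p_raw=p_raw, p_adjusted=p_adj, significant=mask, alpha=alpha, n_perm=n_perm
    )


def fdr_bh(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, rejection mask at ``alpha``); adjusted
    p = min over j >= i of p_(j) * m / j, with monotonicity enforced.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return p_adj.reshape(p.shape), reject.reshape(p.shape)


def bootstrap_ci_mean(
    subject_values: np.ndarray, n_boot: int = 10000, seed: int = 0, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI of the subject mean (resampling subjects)."""
    vals = np.asarray(subject_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    rng = substream(seed, "bootstrap-mean")
    idx = rng.integers(0, vals.shape[0], size=(n_boot, vals.shape[0]))
    means = vals[idx].mean(axis=1)
    lo, hi = np.percentile(means, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def peak_location(curve: np.ndarray, grid: np.ndarray) -> float:
    """Grid value at the curve's global maximum; ties break to the earliest."""
    c = np.asarray(curve, dtype=float)
    g = np.asarray(grid, dtype=float)
    if c.shape != g.shape:
        raise ValueError("curve and grid must align")
    if np.all(np.isnan(c)):
        raise ValueError("all-NaN curve has no peak")
    return float(g[np.nanargmax(c)])


def _boot_peaks(
    curves: np.ndarray, grid: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n_sub = curves.shape[0]
    idx = rng.integers(0, n_sub, size=(n_boot, n_sub))
    means = curves[idx].mean(axis=1)  # (n_boot, n_points)
    return grid[np.argmax(means, axis=1)]


def bootstrap_peak_ci(
    subject_curves: np.ndarray,
    grid: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> PeakEstimate:
    """Bootstrap CI for the peak location of the subject-mean curve."""
    curves = np.atleast_2d(np.asarray(subject_curves, dtype=float))
    if curves.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    grid = np.asarray(grid, dtype=float)
    rng = substream(seed, "bootstrap-peak")
    peaks = _boot_peaks(curves, grid, n_boot, rng)
    lo, hi = np.percentile(peaks, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return PeakEstimate(
        peak=peak_location(curves.mean(axis=0), grid),
        ci=(float(lo), float(hi)),
        n_boot=n_boot,
    )


def bootstrap_peak_difference(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    grid: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
    level: float = 0.95,
    paired: bool = False,
) -> tuple[float, tuple[float, float]]:
    """Bootstrap CI for the difference of two conditions' peak locations.

    Conditions are resampled independently by default (unpaired designs with
    different subject groups); ``paired=True`` resamples the same subject
    indices in both conditions.  A CI containing 0 indicates a non-significant
    peak difference.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per condition")
    grid = np.asarray(grid, dtype=float)
    rng = substream(seed, "bootstrap-peak-difference")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired resampling needs equal group sizes")
        idx = rng.integers(0, a.shape[0], size=(n_boot, a.shape[0]))
        diffs = grid[np.argmax(a[idx].mean(axis=1), axis=1)] - grid[
            np.argmax(b[idx].mean(axis=1), axis=1)
        ]
    else:
        diffs = _boot_peaks(a, grid, n_boot, rng) - _boot_peaks(b, grid, n_boot, rng)
    lo, hi = np.percentile(diffs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    point = peak_location(a.mean(axis=0), grid) - peak_location(b.mean(axis=0), grid)
    return float(point), (float(lo), float(hi))


#: exhaustive enumeration cap for the hierarchy permutation test (8! = 40320)
ENUMERATION_CAP = 40320


def hierarchy_correlation(
    peak_latencies: np.ndarray,
    peak_layers: np.ndarray,
    tail: str = "greater",
    n_mc: int = 100000,
    seed: int = 0,
) -> HierarchyCorrelation:
    """Spearman correlation between two peak vectors with a permutation p.

    The layer vector is permuted over all n! orderings (5040 for the default
    seven features); above ``ENUMERATION_CAP`` orderings a Monte-Carlo
    estimate with ``n_mc`` draws is used and flagged.  The default test is
    one-sided for positive alignment; ``tail='two-sided'`` ranks |r|.
    """
    lat = np.asarray(peak_latencies, dtype=float)
    lay = np.asarray(peak_layers, dtype=float)
    if lat.shape != lay.shape or lat.ndim != 1:
        raise ValueError("peak vectors must be 1-D and of equal length")
    n = lat.size
    if n < 3:
        raise ValueError("need at least 3 features")
    if tail not in ("greater", "two-sided"):
        raise ValueError("tail must be 'greater' or 'two-sided'")

    lat_rank = stats.rankdata(lat)
    lay_rank = stats.rankdata(lay)

    def rs(perm_ranks: np.ndarray) -> float:
        return float(np.corrcoef(lat_rank, perm_ranks)[0, 1])

    observed = rs(lay_rank)
    n_perm = factorial(n)
    if n_perm <= ENUMERATION_CAP:
        null = np.array([rs(lay_rank[list(p)]) for p in permutations(range(n))])
        exhaustive = True
    else:
        rng = substream(seed, "hierarchy-permutation")
        null = np.array([rs(rng.permutation(lay_rank)) for _ in range(n_mc)])
        n_perm = n_mc
        exhaustive = False

    tol = 1e-12
    if tail == "greater":
        count = (null >= observed - tol).sum()
    else:
        count = (np.abs(null) >= abs(observed) - tol).sum()
    if exhaustive:
        p = count / n_perm  # the identity permutation is part of the null set
    else:
        p = (1 + count) / (1 + n_perm)
    return HierarchyCorrelation(
        r_s=observed,
        p_value=float(p),
        n_features=n,
        n_permutations=int(n_perm),
        exhaustive=exhaustive,
        tail=tail,
    )
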