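"""Group-level inference across independent participant subgroups.

Reliable boundary statistics require group-averaged data, so significance
is assessed by splitting the participants into independent subgroups
(e.g. 15 groups of 17–18), recomputing the statistic of interest per
group, and testing its median against zero with a Wilcoxon signed-rank
test; p-values are corrected with Benjamini–Hochberg FDR and a result is
vetoed when the sign of the pooled (all-participant) effect disagrees with
the mean sign across subgroups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupDesign",
    "split_groups",
    "wilcoxon_signed_rank",
    "fdr_bh",
    "sign_consistency",
]

MIN_GROUPS = 5
EXACT_MAX_N = 25


@dataclass(frozen=True)
class GroupDesign:
    """A balanced random partition of subjects into groups (ids 0..n_groups-1)."""

    assignments: np.ndarray  # group id per subject
    n_groups: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", np.asarray(self.assignments, dtype=int))

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == group)


def split_groups(n_subjects: int, n_groups: int, seed: int = 0) -> GroupDesign:
    """Randomly partition subjects into groups whose sizes differ by <= 1."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_subjects < n_groups:
        raise ValueError("need at least one subject per group")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    assignments = np.empty(n_subjects, dtype=int)
    assignments[order] = np.arange(n_subjects) % n_groups
    return GroupDesign(assignments=assignments, n_groups=n_groups, seed=seed)


def _exact_signflip_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided sign-flip p-value of the signed-rank statistic.

    Midranks may be half-integers, so the distribution of 2*W+ over all
    2^n sign assignments is built by a polynomial (subset-sum) recursion;
    valid with ties, feasible for n <= 25.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(values, min_n: int = MIN_GROUPS) -> float:
    """Two-sided signed-rank p-value for median != 0 across groups.

    Missing values and exact zeros are dropped; ties receive midranks.  The
    null distribution is exact (all sign assignments) for n <= 25 and a
    normal approximation with tie correction and continuity correction
    beyond that.  Returns NaN when fewer than ``min_n`` informative values
    remain.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    v = v[v != 0]
    n = v.size
    if n < min_n:
        warnings.warn(f"only {n} informative group values (< {min_n}); p undefined")
        return float("nan")
    ranks = sp_stats.rankdata(np.abs(v))
    w_plus = float(ranks[v > 0].sum())
    if n <= EXACT_MAX_N:
        return _exact_signflip_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    d = w_plus - mean
    z = (d - 0.5 * np.sign(d)) / np.sqrt(var)
    return float(2.0 * sp_stats.norm.sf(abs(z)))


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up over the defined p-values.

    Returns per-test significance flags (missing p-values get False) and
    the largest p-value that passed (NaN when nothing passes).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    ok = np.isfinite(p)
    if not ok.any():
        raise ValueError("no defined p-values")
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.size, dtype=bool)
    reject, _, _, _ = multipletests(p[ok], alpha=q, method="fdr_bh")
    flags[ok] = reject
    crit = float(p[flags].max()) if flags.any() else float("nan")
    return flags, crit


def sign_consistency(pooled_effect: float, group_effects) -> bool:
    """True when the pooled effect's sign matches the mean subgroup effect.

    Significance flags should be vetoed when this is False; a zero mean
    (no direction) also fails the check.
    """
    if not np.isfinite(pooled_effect):
        raise ValueError("pooled effect is undefined")
    g = np.asarray(group_effects, dtype=float)
    g = g[np.isfinite(g)]
    m = g.mean() if g.size else float("nan")
    if not np.isfinite(m) or m == 0 or pooled_effect == 0:
        warnings.warn("sign consistency undecidable (zero or undefined mean); flag False")
        return False
    return bool(np.sign(pooled_effect) == np.sign(m))
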