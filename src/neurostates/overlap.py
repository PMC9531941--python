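"""Boundary time-series algebra: overlap statistics between boundary sets.

A boundary series marks, per timepoint, whether a transition occurs (1, or
a weight) or not (0).  The overlap O between two series is the sum of their
pointwise product; because O grows with the number of boundaries it is
rescaled against the overlap expected by chance, OE = (1/n) * sum(a) *
sum(b):

* absolute overlap  OA = (O - OE) / (sum(s) - OE)  — the proportion of the
  state boundaries in ``s`` coinciding with a boundary in ``e``, 0 at
  chance level and 1 at full coincidence;
* relative overlap  OR = (O - OE) / (min(sum(a), sum(b)) - OE) — rescaled
  by the maximum achievable overlap, so series with very different
  boundary counts are not penalized.

Weighted variants replace the ones in a series by boundary strengths or by
the fraction of searchlights that share the boundary (co-occurrence).
Undefined values (zero denominators) propagate as NaN, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundarySeries",
    "OverlapResult",
    "series_from_segmentation",
    "events_to_series",
    "expected_overlap",
    "absolute_overlap",
    "relative_overlap",
    "weight_by_strength",
    "weight_by_cooccurrence",
    "shared_unique_decomposition",
    "shared_vs_unique_statistic",
    "pairwise_overlap_matrix",
    "matrix_similarity",
]


@dataclass(frozen=True)
class BoundarySeries:
    """Per-timepoint transition series: 0 = no transition, >0 = transition."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("a boundary series is one-dimensional")
        if np.any(v < 0):
            raise ValueError("boundary series entries must be nonnegative")
        if v.size and v[0] != 0:
            raise ValueError("the first timepoint starts the first state and is never a transition")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def is_binary(self) -> bool:
        return bool(np.all(np.isin(self.values, (0.0, 1.0))))

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class OverlapResult:
    """Raw overlap O, chance expectation OE, and the scaled OA and OR."""

    raw: float
    expected: float
    absolute: float
    relative: float


def series_from_segmentation(seg, label: str = "") -> BoundarySeries:
    """Binary boundary series of a segmentation (1-based boundary indices)."""
    v = np.zeros(seg.n_timepoints)
    v[np.asarray(seg.boundaries, dtype=int) - 1] = 1.0
    return BoundarySeries(values=v, label=label)


def events_to_series(
    onsets_s,
    salience,
    tr: float,
    n: int,
    min_salience: int = 5,
) -> BoundarySeries:
    """Convert annotated event onsets into a binary boundary series.

    Observers pressing a key mark event boundaries; ``salience`` counts how
    many observers marked each onset.  Onsets seen by fewer than
    ``min_salience`` observers are dropped; each surviving onset marks the
    TR that contains it (``floor(onset/tr) + 1``, 1-based); several onsets
    in one TR collapse to a single mark.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    sal = np.asarray(salience, dtype=float)
    if onsets.shape != sal.shape:
        raise ValueError("one salience value per onset required")
    if np.any(onsets < 0) or np.any(onsets >= n * tr):
        raise ValueError("event onset outside the scan duration")
    keep = onsets[sal >= min_salience]
    v = np.zeros(n)
    trs = np.floor(keep / tr).astype(int)  # 0-based TR containing the onset
    v[trs] = 1.0
    if v[0] != 0:
        warnings.warn("event onset in the first TR ignored (timepoint 1 is never a transition)")
        v[0] = 0.0
    return BoundarySeries(values=v, label="events")


def _check_n(a: BoundarySeries, b: BoundarySeries) -> None:
    if a.n != b.n:
        raise ValueError(f"series length mismatch: {a.n} vs {b.n}")


def expected_overlap(a: BoundarySeries, b: BoundarySeries) -> float:
    """Chance-level overlap (1/n) * sum(a) * sum(b); valid for weighted series."""
    _check_n(a, b)
    return a.total * b.total / a.n


def _overlap(e: BoundarySeries, s: BoundarySeries) -> OverlapResult:
    O = float(e.values @ s.values)
    OE = expected_overlap(e, s)
    den_abs = s.total - OE
    den_rel = min(e.total, s.total) - OE
    if s.total == 0 or den_abs == 0:
        warnings.warn("absolute overlap undefined (zero denominator); propagating NaN")
        OA = float("nan")
    else:
        OA = (O - OE) / den_abs
    if min(e.total, s.total) == 0 or den_rel == 0:
        warnings.warn("relative overlap undefined (zero denominator); propagating NaN")
        OR = float("nan")
    else:
        OR = (O - OE) / den_rel
    return OverlapResult(raw=O, expected=OE, absolute=OA, relative=OR)


def absolute_overlap(e: BoundarySeries, s: BoundarySeries) -> OverlapResult:
    """Overlap of state series ``s`` with reference ``e``, scaled so that 0 is
    the chance expectation and 1 means every boundary in ``s`` coincides with
    one in ``e``.  ``s`` may be strength- or co-occurrence-weighted."""
    return _overlap(e, s)


def relative_overlap(a: BoundarySeries, b: BoundarySeries) -> OverlapResult:
    """Overlap scaled by the maximum achievable given both boundary counts;
    symmetric in its arguments for binary series."""
    return _overlap(a, b)


def weight_by_strength(s: BoundarySeries, strengths) -> BoundarySeries:
    """Replace the marks of a binary series by boundary strengths, in order."""
    if not s.is_binary:
        raise ValueError("strength weighting starts from a binary series")
    w = np.asarray(strengths, dtype=float)
    marks = np.flatnonzero(s.values)
    if marks.size != w.size:
        raise ValueError(f"{marks.size} marks but {w.size} strengths")
    v = np.zeros(s.n)
    v[marks] = w
    return BoundarySeries(values=v, label=s.label)


def weight_by_cooccurrence(
    s: BoundarySeries, all_series: list[BoundarySeries], scope=None
) -> BoundarySeries:
    """Replace marks by the fraction of in-scope series sharing the boundary.

    ``scope`` indexes into ``all_series`` (e.g. the searchlights of one
    network, or everything for whole-brain co-occurrence); default: all.
    """
    if not s.is_binary:
        raise ValueError("co-occurrence weighting starts from a binary series")
    if scope is None:
        scope = range(len(all_series))
    scope = list(scope)
    if len(scope) == 0:
        raise ValueError("empty scope")
    stack = np.vstack([all_series[i].values for i in scope])
    if stack.shape[1] != s.n:
        raise ValueError("series length mismatch within scope")
    frac = stack.astype(bool).sum(axis=0) / len(scope)
    return BoundarySeries(values=s.values * frac, label=s.label)


def shared_unique_decomposition(
    si: BoundarySeries, sj: BoundarySeries
) -> tuple[BoundarySeries, BoundarySeries, BoundarySeries]:
    """Split two binary series into shared and unique boundary series.

    shared = si * sj elementwise; unique_i = si - shared; unique_j = sj -
    shared.  The decomposition is conservative: shared + unique_i == si and
    shared + unique_j == sj.
    """
    _check_n(si, sj)
    if not (si.is_binary and sj.is_binary):
        raise ValueError("decomposition is defined for binary series")
    shared = si.values * sj.values
    return (
        BoundarySeries(values=shared, label="shared"),
        BoundarySeries(values=si.values - shared, label=f"unique:{si.label}"),
        BoundarySeries(values=sj.values - shared, label=f"unique:{sj.label}"),
    )


def shared_vs_unique_statistic(
    e: BoundarySeries, si: BoundarySeries, sj: BoundarySeries
) -> float:
    """Do shared boundaries align with events better than unique ones?

    Returns OA(e, shared) - max(OA(e, unique_i), OA(e, unique_j)); positive
    when the boundaries common to both series overlap events more than the
    better-overlapping set of unique boundaries.  NaN when any of the three
    decomposed series is empty or its OA is undefined.
    """
    shared, ui, uj = shared_unique_decomposition(si, sj)
    if shared.total == 0 or ui.total == 0 or uj.total == 0:
        warnings.warn("shared/unique statistic undefined: empty decomposed series")
        return float("nan")
    oa_s = absolute_overlap(e, shared).absolute
    oa_i = absolute_overlap(e, ui).absolute
    oa_j = absolute_overlap(e, uj).absolute
    return oa_s - max(oa_i, oa_j)


def pairwise_overlap_matrix(series: list[BoundarySeries]) -> np.ndarray:
    """Symmetric matrix of relative overlaps; diagonal 1, undefined -> NaN."""
    m = len(series)
    if m < 2:
        raise ValueError("need at least 2 series")
    out = np.eye(m)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(m):
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = relative_overlap(series[i], series[j]).relative
    return out


def matrix_similarity(m1: np.ndarray, m2: np.ndarray) -> float:
    """Pearson correlation of lower-triangle entries, NaNs dropped pairwise."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError("matrices must share shape")
    il, jl = np.tril_indices(m1.shape[0], -1)
    a, b = m1[il, jl], m2[il, jl]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 valid entry pairs")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])
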