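"""Spherical searchlight scanning, per-searchlight segmentation, and
projection of searchlight-level scalars back to voxels.

Searchlight centers sit on a step-2 lattice anchored at the mask bounding
box; each searchlight collects the in-mask voxels within a 3-voxel radius
(123 offsets for a full sphere) and is analyzed as one multi-voxel unit.
Searchlights with fewer than 16 in-mask voxels are dropped.  Voxel indices
are 0-based internally and 1-based in written tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from . import gsbs
from .overlap import BoundarySeries, relative_overlap, series_from_segmentation

__all__ = [
    "Searchlight",
    "VoxelMap",
    "SearchlightResult",
    "sphere_offsets",
    "build_searchlights",
    "segment_searchlights",
    "reliability_filter",
    "project_to_voxels",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Searchlight:
    """A sphere of in-mask voxels around a lattice center."""

    center: tuple[int, int, int]
    members: np.ndarray  # (m, 3) integer voxel indices

    @property
    def n_members(self) -> int:
        return self.members.shape[0]


@dataclass(frozen=True)
class VoxelMap:
    """A 3-D scalar field defined on part of a mask; NaN marks exclusion."""

    grid: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class SearchlightResult:
    """Per-searchlight segmentation output at the optimal state count."""

    series: BoundarySeries
    segmentation: gsbs.Segmentation
    curve: gsbs.TDistanceCurve


def sphere_offsets(radius: int = 3) -> np.ndarray:
    """All integer (dx, dy, dz) with dx^2+dy^2+dz^2 <= radius^2, center included."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    r = int(np.ceil(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def build_searchlights(
    mask: np.ndarray, step: int = 2, radius: int = 3, min_voxels: int = 16
) -> list[Searchlight]:
    """Scan a step-`step` lattice of sphere centers across the mask.

    The lattice is anchored at the mask bounding-box minimum; only in-mask
    centers are used, and searchlights keeping fewer than ``min_voxels``
    in-mask members are discarded.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    offs = sphere_offsets(radius)
    lo = np.min(np.argwhere(mask), axis=0)
    hi = np.max(np.argwhere(mask), axis=0)
    axes = [np.arange(lo[d], hi[d] + 1, step) for d in range(3)]
    out: list[Searchlight] = []
    for cx in axes[0]:
        for cy in axes[1]:
            for cz in axes[2]:
                if not mask[cx, cy, cz]:
                    continue
                pts = offs + (cx, cy, cz)
                ok = np.all((pts >= 0) & (pts < mask.shape), axis=1)
                pts = pts[ok]
                pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
                if pts.shape[0] >= min_voxels:
                    out.append(Searchlight(center=(int(cx), int(cy), int(cz)), members=pts))
    return out


def segment_searchlights(
    data4d: np.ndarray,
    searchlights: list[Searchlight],
    k_max: int = 100,
    finetune: bool = True,
) -> list[SearchlightResult | None]:
    """Run GSBS inside every searchlight; failures yield None and a log entry.

    Emits, per searchlight, the binary boundary series of the segmentation
    at the t-distance-optimal number of states.
    """
    data4d = np.asarray(data4d, dtype=float)
    results: list[SearchlightResult | None] = []
    for i, sl in enumerate(searchlights):
        ts = data4d[sl.members[:, 0], sl.members[:, 1], sl.members[:, 2], :].T
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                segs, curve = gsbs.place_boundaries(ts, k_max=k_max, finetune=finetune)
            seg = next(s for s in segs if s.k == curve.optimum_k)
            results.append(
                SearchlightResult(
                    series=series_from_segmentation(seg, label=f"sl{i}"),
                    segmentation=seg,
                    curve=curve,
                )
            )
        except Exception as exc:  # per-searchlight failure must not kill the run
            log.warning("searchlight %d at %s failed: %s", i, sl.center, exc)
            results.append(None)
    return results


def reliability_filter(
    results_a: list[BoundarySeries | None],
    results_b: list[BoundarySeries | None],
    threshold: float = 0.0,
) -> list[int]:
    """Keep searchlights whose boundary sets replicate across two groups.

    A searchlight passes when the relative overlap between its boundary
    series from two independent participant groups is defined and at least
    ``threshold``; undefined overlaps are excluded with a log entry.
    """
    if len(results_a) != len(results_b):
        raise ValueError("both groups must cover the same searchlight list")
    kept: list[int] = []
    for i, (a, b) in enumerate(zip(results_a, results_b)):
        if a is None or b is None:
            log.info("searchlight %d excluded: missing result", i)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = relative_overlap(a, b).relative
        if np.isnan(r):
            log.info("searchlight %d excluded: undefined between-group overlap", i)
            continue
        if r >= threshold:
            kept.append(i)
    return kept


def project_to_voxels(
    scalars,
    searchlights: list[Searchlight],
    mask: np.ndarray,
    min_coverage: float = 0.5,
) -> VoxelMap:
    """Average searchlight scalars onto the voxels they cover.

    Each voxel receives the mean of the defined scalars of the
    searchlights covering it; voxels where fewer than ``min_coverage`` of
    the covering searchlights carry a defined value are marked NaN, as are
    voxels no searchlight covers.
    """
    scalars = np.asarray(scalars, dtype=float)
    if scalars.size != len(searchlights):
        raise ValueError("one scalar per searchlight required")
    mask = np.asarray(mask, dtype=bool)
    total = np.zeros(mask.shape)
    defined = np.zeros(mask.shape)
    acc = np.zeros(mask.shape)
    for val, sl in zip(scalars, searchlights):
        ix, iy, iz = sl.members.T
        total[ix, iy, iz] += 1
        if np.isfinite(val):
            defined[ix, iy, iz] += 1
            acc[ix, iy, iz] += val
    grid = np.full(mask.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = (total > 0) & (defined / np.maximum(total, 1) >= min_coverage) & (defined > 0)
        grid[ok] = acc[ok] / defined[ok]
    grid[~mask] = np.nan
    return VoxelMap(grid=grid, mask=mask)
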