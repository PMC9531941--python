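"""Synthetic multi-region fMRI datasets with planted state boundaries.

The generator emulates the structure the segmentation pipeline targets:
each region alternates between neural states, each state having a distinct
multi-voxel mean pattern (iid standard normal per voxel) held constant for
the state's duration; per-subject Gaussian noise is added on top, and the
pattern time course can optionally be blurred with the canonical HRF.

Boundary sharing is organized hierarchically.  Networks are ordered from
slow (few states) to fast (many states); the fastest network's boundary
pool is drawn first and slower networks copy each of their boundaries from
the next-faster pool with probability ``nestedness`` (drawing a fresh
location otherwise), so that at nestedness 1 slow boundaries are fully
nested inside fast ones.  Regions copy from their network's pool the same
way.  Event boundaries — the moments human observers would report as a
transition between meaningful units — are a random subset (default half)
of the slowest network's pool.

States are at least 2 TRs long so that within-state correlations (and
hence the t-distance) are always defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import BoldMatrix, canonical_hrf, hrf_convolve

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_ground_truth",
    "generate_subject_data",
    "generate_dataset",
    "write_dataset",
    "tile_regions_to_volume",
]

_MIN_STATE_LEN = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic multi-region, multi-subject dataset.

    ``states_per_region`` is an inclusive (min, max) range; the per-network
    state counts are spread evenly across it, slowest network first.
    ``nestedness`` in [0, 1] is the probability that a slower region's
    boundary is copied from the faster set rather than drawn fresh.
    ``noise_sd`` is the ratio of noise SD to pattern SD (patterns are unit
    SD by construction).  ``ar_coef`` optionally gives the noise an AR(1)
    temporal structure with the same marginal SD.
    """

    n_timepoints: int = 193
    tr: float = 2.47
    n_voxels_per_region: int = 40
    n_regions: int = 4
    n_networks: int = 2
    states_per_region: tuple[int, int] = (8, 15)
    nestedness: float = 0.5
    noise_sd: float = 1.0
    n_subjects: int = 20
    hrf_convolve: bool = False
    ar_coef: float = 0.0
    event_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.states_per_region
        if lo < 2:
            raise ValueError("states_per_region must be >= 2")
        if hi < lo:
            raise ValueError("states_per_region range must be (min, max) with min <= max")
        if self.n_voxels_per_region < 2:
            raise ValueError("n_voxels_per_region must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.nestedness <= 1.0:
            raise ValueError("nestedness must lie in [0, 1]")
        if self.n_regions < 1 or self.n_networks < 1 or self.n_networks > self.n_regions:
            raise ValueError("need 1 <= n_networks <= n_regions")
        if hi > self.n_timepoints / 2:
            raise ValueError(
                f"{hi} states of >= {_MIN_STATE_LEN} TRs do not fit in "
                f"{self.n_timepoints} timepoints"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Planted boundaries: per-region sets, events, and network labels.

    Boundary locations are 1-based TR indices in [2, n_timepoints]
    (timepoint 1 starts the first state and is never a boundary).
    """

    n_timepoints: int
    tr: float
    regions: dict  # region_id -> sorted ndarray of boundary TRs
    event_boundaries: np.ndarray
    network_assignment: dict  # region_id -> network index (0 = slowest)

    def __post_init__(self) -> None:
        for rid, b in self.regions.items():
            b = np.asarray(b, dtype=int)
            if b.size and (b[0] < 2 or b[-1] > self.n_timepoints or np.any(np.diff(b) <= 0)):
                raise ValueError(f"region {rid}: boundaries must be strictly increasing in [2, n]")


def _sample_boundaries(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k boundary locations, uniform over sets with all states >= 2 TRs.

    Bijection trick: gap-2 sets in [3, n-1] correspond one-to-one to plain
    k-subsets of a shrunken range, so sampling stays uniform.
    """
    lo, hi = 3, n - 1
    span = hi - _MIN_STATE_LEN * (k - 1)
    if k == 0:
        return np.array([], dtype=int)
    if span < lo + k - 1:
        raise ValueError(f"cannot place {k} boundaries with {_MIN_STATE_LEN}-TR states in n={n}")
    c = np.sort(rng.choice(np.arange(lo, span + 1), size=k, replace=False))
    return c + _MIN_STATE_LEN * np.arange(k)


def _fresh_draws(rng: np.random.Generator, n: int, existing: np.ndarray, count: int) -> np.ndarray:
    """Draw `count` extra boundaries keeping >= 2 TR distance to all chosen."""
    chosen = list(existing)
    for _ in range(count):
        for _attempt in range(200 * n):
            cand = int(rng.integers(3, n))  # [3, n-1]
            if all(abs(cand - c) >= _MIN_STATE_LEN for c in chosen):
                chosen.append(cand)
                break
        else:
            raise RuntimeError("could not place a boundary with the minimum state length")
    return np.sort(np.asarray(chosen, dtype=int))


def _copy_with_nestedness(
    rng: np.random.Generator, n: int, source: np.ndarray, k: int, nestedness: float
) -> np.ndarray:
    """Boundary set of size k: each slot copied from `source` w.p. nestedness."""
    m = int(rng.binomial(min(k, source.size), nestedness))
    copied = np.sort(rng.choice(source, size=m, replace=False)) if m else np.array([], dtype=int)
    return _fresh_draws(rng, n, copied, k - m)


def generate_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Plant nested boundary sets for every region plus matching events."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_timepoints
    lo, hi = cfg.states_per_region
    counts = np.round(np.linspace(lo, hi, cfg.n_networks)).astype(int)  # slowest first

    # network pools, fastest built first so slower networks can nest into it
    pools: list[np.ndarray | None] = [None] * cfg.n_networks
    pools[-1] = _sample_boundaries(rng, n, counts[-1] - 1)
    for net in range(cfg.n_networks - 2, -1, -1):
        pools[net] = _copy_with_nestedness(rng, n, pools[net + 1], counts[net] - 1, cfg.nestedness)

    regions: dict[int, np.ndarray] = {}
    assignment: dict[int, int] = {}
    for rid in range(cfg.n_regions):
        net = rid % cfg.n_networks
        assignment[rid] = net
        regions[rid] = _copy_with_nestedness(rng, n, pools[net], counts[net] - 1, cfg.nestedness)

    pool0 = pools[0]
    n_events = max(1, int(round(cfg.event_fraction * pool0.size)))
    events = np.sort(rng.choice(pool0, size=n_events, replace=False))
    return GroundTruth(
        n_timepoints=n,
        tr=cfg.tr,
        regions=regions,
        event_boundaries=events,
        network_assignment=assignment,
    )


def _labels(n: int, boundaries: np.ndarray) -> np.ndarray:
    lab = np.zeros(n, dtype=int)
    lab[np.asarray(boundaries, dtype=int) - 1] = 1
    return np.cumsum(lab)


def generate_subject_data(
    gt: GroundTruth, region_id, cfg: SimulationConfig, subject_seed: int
) -> BoldMatrix:
    """One subject's timepoints x voxels matrix for one region.

    The state mean patterns depend only on (cfg.seed, region) — they are
    the shared signal; the additive noise depends on ``subject_seed``.
    """
    if region_id not in gt.regions:
        raise KeyError(f"unknown region {region_id!r}")
    bounds = gt.regions[region_id]
    lab = _labels(gt.n_timepoints, bounds)
    k = lab[-1] + 1
    pat_rng = np.random.default_rng([cfg.seed % (2**31), 7919, int(region_id)])
    patterns = pat_rng.standard_normal((k, cfg.n_voxels_per_region))
    signal = patterns[lab]
    if cfg.hrf_convolve:
        signal = hrf_convolve(signal, canonical_hrf(cfg.tr))
    noise_rng = np.random.default_rng(
        [cfg.seed % (2**31), 104729, int(region_id), int(subject_seed) % (2**31)]
    )
    eps = noise_rng.standard_normal(signal.shape)
    if cfg.ar_coef > 0.0:
        phi = cfg.ar_coef
        ar = np.empty_like(eps)
        ar[0] = eps[0]
        scale = np.sqrt(1.0 - phi**2)
        for t in range(1, eps.shape[0]):
            ar[t] = phi * ar[t - 1] + scale * eps[t]
        eps = ar
    return BoldMatrix(values=signal + cfg.noise_sd * eps, tr=cfg.tr)


def generate_dataset(
    cfg: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[GroundTruth, dict, pd.DataFrame]:
    """Full dataset: ground truth, per-(region, subject) matrices, events.

    The events table carries ``onset_s`` (mid-TR onsets of the planted
    event boundaries) and ``salience`` (simulated observer counts, 5–16).
    When ``out_dir`` is given the dataset is also written to disk via
    :func:`write_dataset`.
    """
    gt = generate_ground_truth(cfg)
    data = {
        (rid, s): generate_subject_data(gt, rid, cfg, subject_seed=s)
        for rid in gt.regions
        for s in range(cfg.n_subjects)
    }
    sal_rng = np.random.default_rng([cfg.seed % (2**31), 65537])
    events = pd.DataFrame(
        {
            "onset_s": (gt.event_boundaries - 1) * cfg.tr + cfg.tr / 2.0,
            "salience": sal_rng.integers(5, 17, size=gt.event_boundaries.size),
        }
    )
    if out_dir is not None:
        write_dataset(gt, data, events, cfg, Path(out_dir))
    return gt, data, events


def _region_block_shape(v: int) -> tuple[int, int, int]:
    """Near-cubic integer factorization of the per-region voxel count."""
    bz = max(d for d in range(1, int(round(v ** (1 / 3))) + 1) if v % d == 0)
    rest = v // bz
    by = max(d for d in range(1, int(np.sqrt(rest)) + 1) if rest % d == 0)
    return rest // by, by, bz


def tile_regions_to_volume(
    data: dict, cfg: SimulationConfig, subject: int
) -> tuple[np.ndarray, np.ndarray]:
    """Tile one subject's regions into a 4-D volume plus a region label map.

    Regions become near-cubic blocks stacked along the first axis with a
    1-voxel gap; the label map holds region_id + 1 (0 = outside).
    """
    bx, by, bz = _region_block_shape(cfg.n_voxels_per_region)
    n_reg = cfg.n_regions
    shape = ((bx + 1) * n_reg - 1, by, bz)
    vol = np.zeros(shape + (cfg.n_timepoints,))
    labelmap = np.zeros(shape, dtype=int)
    for rid in range(n_reg):
        x0 = rid * (bx + 1)
        block = data[(rid, subject)].values.T.reshape(bx, by, bz, cfg.n_timepoints)
        vol[x0 : x0 + bx] = block
        labelmap[x0 : x0 + bx] = rid + 1
    return vol, labelmap


def write_dataset(
    gt: GroundTruth, data: dict, events: pd.DataFrame, cfg: SimulationConfig, out_dir: Path
) -> None:
    """Write NIfTI volumes per subject, region labels, events TSV, truth JSON."""
    import nibabel as nib

    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise FileNotFoundError(f"parent of output directory does not exist: {out_dir}")
    out_dir.mkdir(exist_ok=True)
    affine = np.eye(4)
    labelmap = None
    for s in range(cfg.n_subjects):
        vol, labelmap = tile_regions_to_volume(data, cfg, s)
        img = nib.Nifti1Image(vol.astype(np.float32), affine)
        img.header.set_zooms((1.0, 1.0, 1.0, cfg.tr))
        nib.save(img, out_dir / f"subject{s:03d}.nii")
    nib.save(nib.Nifti1Image(labelmap.astype(np.int16), affine), out_dir / "regions.nii")
    events.to_csv(out_dir / "events.tsv", sep="\t", index=False)
    truth = {
        "n_timepoints": gt.n_timepoints,
        "tr": gt.tr,
        "regions": {str(r): np.asarray(b).tolist() for r, b in gt.regions.items()},
        "event_boundaries": np.asarray(gt.event_boundaries).tolist(),
        "network_assignment": {str(r): int(v) for r, v in gt.network_assignment.items()},
        "config": asdict(cfg),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
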