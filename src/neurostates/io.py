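"""NIfTI and TSV round-tripping used by the command-line pipelines."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .overlap import BoundarySeries
from .preprocess import BoldMatrix
from .searchlight import Searchlight, VoxelMap

__all__ = [
    "load_volume",
    "save_volume",
    "load_mask",
    "extract_timecourses",
    "save_voxelmap",
    "series_to_frame",
    "frame_to_series",
    "save_matrix",
    "load_matrix",
]


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    """Load a 4-D NIfTI; returns (X, Y, Z, T) data and the TR from the header."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return data, tr


def save_volume(path: str | Path, data: np.ndarray, tr: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), np.eye(4))
    if tr is not None and data.ndim == 4:
        img.header.set_zooms((1.0, 1.0, 1.0, tr))
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    return data > 0


def extract_timecourses(data4d: np.ndarray, mask: np.ndarray, tr: float) -> BoldMatrix:
    """Timepoints x voxels matrix of the in-mask voxels (axis order preserved)."""
    idx = np.argwhere(mask)
    return BoldMatrix(values=data4d[idx[:, 0], idx[:, 1], idx[:, 2], :].T, tr=tr)


def save_voxelmap(path: str | Path, vmap: VoxelMap) -> None:
    nib.save(nib.Nifti1Image(vmap.grid.astype(np.float32), np.eye(4)), str(path))


def series_to_frame(series: BoundarySeries) -> pd.DataFrame:
    """Boundary series as a TSV-ready table (1-based timepoints)."""
    return pd.DataFrame({"timepoint": np.arange(1, series.n + 1), "value": series.values})


def frame_to_series(df: pd.DataFrame, label: str = "") -> BoundarySeries:
    df = df.sort_values("timepoint")
    return BoundarySeries(values=df["value"].to_numpy(dtype=float), label=label)


def save_matrix(path: str | Path, m: np.ndarray, labels=None) -> None:
    labels = labels if labels is not None else [f"sl{i}" for i in range(m.shape[0])]
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, sep="\t")


def load_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=float)


def searchlight_table(
    searchlights: list[Searchlight], ks, medians, iqr_ratios
) -> pd.DataFrame:
    """Per-searchlight summary table; voxel coordinates reported 1-based."""
    centers = np.array([sl.center for sl in searchlights], dtype=int) + 1
    return pd.DataFrame(
        {
            "searchlight": np.arange(len(searchlights)),
            "center_x": centers[:, 0],
            "center_y": centers[:, 1],
            "center_z": centers[:, 2],
            "n_members": [sl.n_members for sl in searchlights],
            "k": ks,
            "median_duration_s": medians,
            "iqr_over_median": iqr_ratios,
        }
    )
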