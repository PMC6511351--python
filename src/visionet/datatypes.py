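"""Core in-memory containers for the pipeline.

Light dataclass wrappers around numpy arrays + affines; NIfTI I/O lives in
:mod:`visionet.io`. Containers validate their own invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NETWORKS = ("PVN", "HVN", "VSN")

MOTION_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass
class Bold4D:
    """A single-subject BOLD run: (x, y, z, t) array, affine, TR in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD run must contain at least one volume")
        if self.tr <= 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class AtlasNetworks:
    """Integer ROI label volume plus the ROI -> network assignment.

    Label 0 is background; labels 1..R are ROIs.  Every nonzero label must be
    assigned to one of PVN / HVN / VSN.
    """

    labels: np.ndarray
    assignment: dict[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D volume")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.assignment)
        if missing:
            raise ValueError(f"labels without network assignment: {sorted(missing)}")
        bad = {n for n in self.assignment.values() if n not in NETWORKS}
        if bad:
            raise ValueError(f"unknown network names: {sorted(bad)}")

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.assignment)

    def rois_in(self, network: str) -> list[int]:
        return [r for r in self.roi_ids if self.assignment[r] == network]

    def network_sizes(self) -> dict[str, int]:
        return {n: len(self.rois_in(n)) for n in NETWORKS}


@dataclass
class GrayMatterMap:
    """Modulated gray-matter density map for one subject."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("gray-matter map must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("gray-matter map contains non-finite values")


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    Columns tx, ty, tz are translations in mm; rx, ry, rz rotations in
    degrees.  One row per acquired volume.
    """

    table: pd.DataFrame
    ground_truth_exclude: bool | None = None

    def __post_init__(self) -> None:
        if tuple(self.table.columns) != MOTION_COLUMNS:
            raise ValueError(
                f"motion trace must have columns {MOTION_COLUMNS}, "
                f"got {tuple(self.table.columns)}"
            )
        if len(self.table) < 1:
            raise ValueError("motion trace is empty")

    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


@dataclass
class RoiTimeSeries:
    """ROI-mean signals: rows follow ``roi_ids`` order, columns are time."""

    matrix: np.ndarray
    roi_ids: list[int]
    tr: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("ROI time-series matrix must be 2D (roi x time)")
        if self.matrix.shape[0] != len(self.roi_ids):
            raise ValueError("row count does not match roi_ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("ROI time series contain missing values")


@dataclass
class RoiFCMatrix:
    """Pairwise ROI Pearson correlations and their Fisher z transform."""

    r: np.ndarray
    z: np.ndarray
    roi_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.r.shape != self.z.shape or self.r.ndim != 2:
            raise ValueError("r and z must be square matrices of equal shape")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        off = ~np.eye(self.r.shape[0], dtype=bool)
        if np.any(np.abs(self.r[off]) > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
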