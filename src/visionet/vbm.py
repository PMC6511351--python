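"""Voxel-based morphometry group statistics.

Voxel-wise two-sample comparison of gray-matter density maps with
non-parametric inference: pooled-variance t maps, threshold-free cluster
enhancement (TFCE, E = 0.5, H = 2 by default), and family-wise error
control by the max-statistic permutation null (group labels permuted, the
maximum TFCE value over voxels recorded per permutation, and each voxel's
corrected p computed as the fraction of permutation maxima at or above its
observed TFCE — with the customary +1 in numerator and denominator).

Positive and negative contrasts are enhanced separately on t and -t; the
default alternative is one-sided on the configured contrast (the study
design expects gray-matter reductions in patients, i.e. control > patient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from ._tfce import tfce_positive
from .datatypes import GrayMatterMap

__all__ = [
    "TFCEParams",
    "ClusterRecord",
    "voxelwise_ttest",
    "tfce_enhance",
    "permutation_fwe",
    "report_clusters",
    "PermutationVBM",
]


@dataclass(frozen=True)
class TFCEParams:
    """TFCE exponents and discretization.

    E weighs cluster extent, H cluster height; the defaults are the
    method's canonical choices.  ``dh = None`` uses max(stat)/100 per map.
    """

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.E <= 0 or self.H <= 0:
            raise ValueError("E and H must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class ClusterRecord:
    size: int
    peak_xyz_mm: tuple[float, float, float]
    peak_p: float
    label: str = ""


def _stack(maps: list[GrayMatterMap] | list[np.ndarray]) -> np.ndarray:
    arrays = [m.data if isinstance(m, GrayMatterMap) else np.asarray(m, float) for m in maps]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"maps have inconsistent shapes: {sorted(shapes)}")
    return np.stack(arrays, axis=0)


def _pooled_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t (a minus b) along axis 0; 0/0 -> 0."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    return t


def voxelwise_ttest(
    group_a: list[GrayMatterMap] | list[np.ndarray],
    group_b: list[GrayMatterMap] | list[np.ndarray],
) -> np.ndarray:
    """Per-voxel pooled two-sample t map (group_a minus group_b).

    Voxels with zero pooled variance (e.g. empty background in synthetic
    data) get t = 0 rather than NaN.
    """
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 maps per group")
    return _pooled_t(a, b)


def tfce_enhance(stat: np.ndarray, params: TFCEParams = TFCEParams()) -> np.ndarray:
    """Signed TFCE map: positive and negative lobes enhanced separately."""
    stat = np.asarray(stat, dtype=float)
    pos = tfce_positive(stat, params.E, params.H, params.dh, params.connectivity)
    neg = tfce_positive(-stat, params.E, params.H, params.dh, params.connectivity)
    return pos - neg


def _null_and_observed(
    data: np.ndarray,
    n_a: int,
    perms: np.ndarray,
    params: TFCEParams,
    alternative: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed TFCE map and the max-TFCE permutation null."""
    shape = data.shape[1:]
    flat = data.reshape(data.shape[0], -1)

    def tfce_of(labels_a: np.ndarray) -> np.ndarray:
        a = flat[labels_a]
        b = flat[~labels_a]
        t = _pooled_t(a, b).reshape(shape)
        if alternative == "greater":
            return tfce_positive(t, params.E, params.H, params.dh, params.connectivity)
        return np.abs(tfce_enhance(t, params))

    obs_mask = np.zeros(data.shape[0], dtype=bool)
    obs_mask[:n_a] = True
    observed = tfce_of(obs_mask)
    null_max = np.empty(perms.shape[0])
    for i, perm in enumerate(perms):
        mask = np.zeros(data.shape[0], dtype=bool)
        mask[perm] = True
        null_max[i] = tfce_of(mask).max()
    return observed, null_max


def permutation_fwe(
    group_a: list[GrayMatterMap] | list[np.ndarray],
    group_b: list[GrayMatterMap] | list[np.ndarray],
    params: TFCEParams = TFCEParams(),
    n_perm: int = 5000,
    seed: int | None = None,
    alternative: str = "greater",
    exhaustive: bool = False,
) -> np.ndarray:
    """FWE-corrected voxel p map from the max-TFCE permutation null.

    corrected p = (1 + #{permutation max >= observed TFCE}) / (1 + n_perm),
    so p is floored at 1/(n_perm + 1).  ``alternative="greater"`` tests
    group_a > group_b on the enhanced map; ``"two-sided"`` uses |TFCE| of
    the signed enhancement.  ``exhaustive=True`` enumerates every label
    assignment (feasible only for small cohorts) instead of sampling.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    a, b = _stack(group_a), _stack(group_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("group map shapes differ")
    data = np.concatenate([a, b], axis=0)
    n_a, n = a.shape[0], a.shape[0] + b.shape[0]
    if exhaustive:
        from itertools import combinations

        perms = np.array([list(c) for c in combinations(range(n), n_a)])
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be at least 1")
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n)[:n_a] for _ in range(n_perm)])
    observed, null_max = _null_and_observed(data, n_a, perms, params, alternative)
    exceed = (null_max[:, None] >= observed.ravel()[None, :] - 1e-12).sum(axis=0)
    pmap = (1.0 + exceed) / (1.0 + perms.shape[0])
    return pmap.reshape(a.shape[1:])


def report_clusters(
    pmap: np.ndarray,
    alpha: float = 0.0002,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> list[ClusterRecord]:
    """Connected components of {corrected p < alpha}, largest first.

    The peak voxel is the one with the smallest p inside the cluster,
    reported in world (mm) coordinates through the affine (identity if
    omitted).  An empty list means nothing survived the threshold.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    pmap = np.asarray(pmap, dtype=float)
    affine = np.eye(4) if affine is None else np.asarray(affine, float)
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    labelled, n_clusters = ndimage.label(pmap < alpha, structure=structure)
    records = []
    for c in range(1, n_clusters + 1):
        voxels = np.argwhere(labelled == c)
        pvals = pmap[tuple(voxels.T)]
        peak = voxels[np.argmin(pvals)]
        world = affine @ np.array([*peak, 1.0])
        records.append(
            ClusterRecord(
                size=int(len(voxels)),
                peak_xyz_mm=tuple(np.round(world[:3], 6)),
                peak_p=float(pvals.min()),
            )
        )
    records.sort(key=lambda r: (-r.size, r.peak_p))
    return records


def clusters_to_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_size_voxels": r.size,
                "x_mm": r.peak_xyz_mm[0],
                "y_mm": r.peak_xyz_mm[1],
                "z_mm": r.peak_xyz_mm[2],
                "peak_p": r.peak_p,
                "label": r.label,
            }
            for r in records
        ],
        columns=["cluster_size_voxels", "x_mm", "y_mm", "z_mm", "peak_p", "label"],
    )


class PermutationVBM(BaseEstimator):
    """sklearn-style estimator for the whole VBM stage.

    ``fit(maps, y)`` takes a list of 3D maps (or GrayMatterMap) and binary
    labels (1 = group A, 0 = group B) and exposes the fitted artefacts as
    ``stat_map_``, ``tfce_map_``, ``pmap_`` and ``clusters_``.
    """

    def __init__(
        self,
        E: float = 0.5,
        H: float = 2.0,
        dh: float | None = None,
        connectivity: int = 26,
        n_perm: int = 5000,
        alpha: float = 0.0002,
        alternative: str = "greater",
        smooth_sigma_mm: float = 0.0,
        voxel_size_mm: float = 1.0,
        random_state: int | None = None,
    ):
        self.E = E
        self.H = H
        self.dh = dh
        self.connectivity = connectivity
        self.n_perm = n_perm
        self.alpha = alpha
        self.alternative = alternative
        self.smooth_sigma_mm = smooth_sigma_mm
        self.voxel_size_mm = voxel_size_mm
        self.random_state = random_state

    def fit(self, X, y, affine: np.ndarray | None = None) -> "PermutationVBM":
        y = np.asarray(y).astype(bool)
        maps = [m.data if isinstance(m, GrayMatterMap) else np.asarray(m, float) for m in X]
        if self.smooth_sigma_mm > 0:
            from scipy.ndimage import gaussian_filter

            sig = self.smooth_sigma_mm / self.voxel_size_mm
            maps = [gaussian_filter(m, sig, mode="nearest") for m in maps]
        a = [m for m, lab in zip(maps, y) if lab]
        b = [m for m, lab in zip(maps, y) if not lab]
        params = TFCEParams(self.E, self.H, self.dh, self.connectivity)
        self.stat_map_ = voxelwise_ttest(a, b)
        self.tfce_map_ = tfce_enhance(self.stat_map_, params)
        self.pmap_ = permutation_fwe(
            a,
            b,
            params=params,
            n_perm=self.n_perm,
            seed=self.random_state,
            alternative=self.alternative,
        )
        self.clusters_ = report_clusters(
            self.pmap_, self.alpha, self.connectivity, affine
        )
        return self
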