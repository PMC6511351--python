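"""Network functional connectivity: the study's core statistic.

Per subject: mean time series per atlas ROI, pairwise Pearson correlations,
Fisher r-to-z, then averaging of the z values within each network (intra-FC)
and between each pair of networks (inter-FC) into a symmetric 3x3 matrix
indexed (PVN, HVN, VSN).  Group comparison is a pooled two-sample t test
per matrix entry with Benjamini-Hochberg FDR control applied separately
within the intra family (3 tests) and the inter family (3 tests) — the two
"subsystems".  Clinical correlation is plain Pearson r plus a least-squares
line.

Averaging order: pairwise r values are Fisher-transformed *before* any
averaging (both within subject and across subjects); an r-scale-first
option is exposed for sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .datatypes import NETWORKS, AtlasNetworks, Bold4D, RoiFCMatrix, RoiTimeSeries

__all__ = [
    "extract_roi_timeseries",
    "pearson_r",
    "fisher_z",
    "roi_fc_matrix",
    "network_matrix",
    "ttest_two_sample",
    "ttest_from_summary",
    "chi_square_2x2",
    "fdr_bh",
    "compare_groups",
    "correlate_clinical",
    "GroupFCComparison",
    "NetworkConnectivityMeasure",
]

_CLAMP = 1.0 - 1e-7


def extract_roi_timeseries(run: Bold4D, atlas: AtlasNetworks) -> RoiTimeSeries:
    """Unweighted mean BOLD signal over each ROI's voxels, per time point."""
    if run.grid_shape != atlas.labels.shape:
        raise ValueError(
            f"BOLD grid {run.grid_shape} does not match atlas {atlas.labels.shape}"
        )
    rows = []
    for roi in atlas.roi_ids:
        mask = atlas.labels == roi
        if not mask.any():
            raise ValueError(f"ROI {roi} has no voxels in the atlas volume")
        rows.append(run.data[mask].mean(axis=0))
    return RoiTimeSeries(matrix=np.asarray(rows, dtype=float), roi_ids=atlas.roi_ids, tr=run.tr)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two equally long series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two 1D series of equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.clip(stats.pearsonr(x, y).statistic, -1.0, 1.0))


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilizing z = atanh(r); |r| >= 1 is clamped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        warnings.warn(
            "correlation at or beyond +/-1 clamped before Fisher transform",
            RuntimeWarning,
        )
        r = np.clip(r, -_CLAMP, _CLAMP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def roi_fc_matrix(ts: RoiTimeSeries) -> RoiFCMatrix:
    """Pairwise ROI Pearson matrix and its Fisher transform."""
    r = np.corrcoef(ts.matrix)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    off = ~np.eye(r.shape[0], dtype=bool)
    z = np.zeros_like(r)
    z[off] = fisher_z(r[off])
    return RoiFCMatrix(r=r, z=z, roi_ids=list(ts.roi_ids))


def network_matrix(
    fc: RoiFCMatrix, atlas: AtlasNetworks, scale: str = "z"
) -> pd.DataFrame:
    """3x3 network matrix: mean pairwise FC within/between networks.

    Diagonal entries average the unordered within-network ROI pairs
    (intra-FC); off-diagonal entries average all ROI pairs straddling the
    two networks (inter-FC).  ``scale="z"`` (default) averages Fisher-z
    values; ``scale="r"`` averages raw correlations then transforms, for
    sensitivity checks.  A single-ROI network has no within pair: its intra
    entry is NaN.
    """
    if scale not in ("z", "r"):
        raise ValueError("scale must be 'z' or 'r'")
    ids = fc.roi_ids if fc.roi_ids else atlas.roi_ids
    unassigned = [i for i in ids if i not in atlas.assignment]
    if unassigned:
        raise ValueError(f"ROIs without network assignment: {unassigned}")
    idx = {roi: k for k, roi in enumerate(ids)}
    members = {n: [idx[r] for r in atlas.rois_in(n) if r in idx] for n in NETWORKS}
    values = fc.z if scale == "z" else fc.r
    out = np.full((3, 3), np.nan)
    for i, ni in enumerate(NETWORKS):
        for j, nj in enumerate(NETWORKS):
            if j < i:
                continue
            if i == j:
                rows = members[ni]
                pairs = [(a, b) for k, a in enumerate(rows) for b in rows[k + 1 :]]
            else:
                pairs = [(a, b) for a in members[ni] for b in members[nj]]
            if pairs:
                m = float(np.mean([values[a, b] for a, b in pairs]))
                if scale == "r":
                    m = float(fisher_z(m))
                out[i, j] = out[j, i] = m
    return pd.DataFrame(out, index=list(NETWORKS), columns=list(NETWORKS))


def ttest_two_sample(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t test (pooled by default; Welch optional): (t, two-tailed p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def ttest_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Pooled two-sample t test from printed summary statistics."""
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 df."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any() or table.sum() == 0:
        raise ValueError("need a non-negative 2x2 table with positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(raw_p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p, boolean rejection set)."""
    raw_p = np.asarray(raw_p, dtype=float)
    if raw_p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((raw_p < 0) | (raw_p > 1)) or not np.all(np.isfinite(raw_p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(raw_p, alpha=alpha, method="fdr_bh")
    return adjusted, reject


_PAIRS = [("PVN", "PVN"), ("HVN", "HVN"), ("VSN", "VSN"),
          ("PVN", "HVN"), ("PVN", "VSN"), ("HVN", "VSN")]


@dataclass
class GroupFCComparison:
    """Per-pair group test table plus group-mean and difference matrices."""

    table: pd.DataFrame  # one row per network pair
    patient_mean: pd.DataFrame  # 3x3
    control_mean: pd.DataFrame  # 3x3
    difference: pd.DataFrame  # patients minus controls, 3x3


def _subject_stack(matrices: list[pd.DataFrame]) -> np.ndarray:
    ref = list(NETWORKS)
    stack = []
    for m in matrices:
        if list(m.index) != ref or list(m.columns) != ref:
            raise ValueError("inconsistent network ordering across subjects")
        stack.append(m.to_numpy())
    return np.asarray(stack)


def compare_groups(
    patients: list[pd.DataFrame],
    controls: list[pd.DataFrame],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupFCComparison:
    """Entrywise group comparison of subject-level 3x3 network matrices.

    Six tests (3 intra + 3 inter); BH-FDR is applied separately within the
    intra and inter families, mirroring the subsystem-wise control of the
    study design.  Entries that are NaN for every subject (single-ROI
    network intra) are reported with NaN statistics and never rejected.
    """
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 subjects per group")
    pat = _subject_stack(patients)
    con = _subject_stack(controls)
    nidx = {n: i for i, n in enumerate(NETWORKS)}
    rows = []
    for na, nb in _PAIRS:
        i, j = nidx[na], nidx[nb]
        a, b = pat[:, i, j], con[:, i, j]
        if np.isnan(a).all() or np.isnan(b).all():
            t = p = np.nan
        else:
            t, p = ttest_two_sample(a[~np.isnan(a)], b[~np.isnan(b)], equal_var=equal_var)
        rows.append(
            {
                "pair": na if na == nb else f"{na}-{nb}",
                "family": "intra" if na == nb else "inter",
                "patient_mean": float(np.nanmean(a)) if not np.isnan(a).all() else np.nan,
                "patient_sd": float(np.nanstd(a, ddof=1)) if not np.isnan(a).all() else np.nan,
                "control_mean": float(np.nanmean(b)) if not np.isnan(b).all() else np.nan,
                "control_sd": float(np.nanstd(b, ddof=1)) if not np.isnan(b).all() else np.nan,
                "t": t,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    table["significant"] = False
    for family in ("intra", "inter"):
        sel = (table["family"] == family) & table["p_raw"].notna()
        if sel.any():
            adj, rej = fdr_bh(table.loc[sel, "p_raw"].to_numpy(), alpha=alpha)
            table.loc[sel, "p_fdr"] = adj
            table.loc[sel, "significant"] = rej
    nets = list(NETWORKS)
    pmean = pd.DataFrame(np.nanmean(pat, axis=0), index=nets, columns=nets)
    cmean = pd.DataFrame(np.nanmean(con, axis=0), index=nets, columns=nets)
    return GroupFCComparison(
        table=table,
        patient_mean=pmean,
        control_mean=cmean,
        difference=pmean - cmean,
    )


def correlate_clinical(
    fc_values: np.ndarray, covariate: np.ndarray, alpha: float = 0.05
) -> dict:
    """Pearson correlation and least-squares line between FC and a covariate."""
    fc = np.asarray(fc_values, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if fc.shape != cov.shape or fc.ndim != 1 or fc.size < 3:
        raise ValueError("need paired 1D samples of length >= 3")
    if np.ptp(cov) == 0 or np.ptp(fc) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(fc, cov)
    fit = stats.linregress(fc, cov)
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "significant": bool(p < alpha),
    }


class NetworkConnectivityMeasure(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: ROI time series -> 3x3 network matrices.

    ``transform`` maps a list of (time x ROI) arrays (sklearn sample
    convention, as produced by :class:`TemporalBandpass`) or
    :class:`RoiTimeSeries` to a list of 3x3 network-FC DataFrames on the
    Fisher-z scale.
    """

    def __init__(self, atlas: AtlasNetworks | None = None, scale: str = "z"):
        self.atlas = atlas
        self.scale = scale

    def fit(self, X=None, y=None) -> "NetworkConnectivityMeasure":
        if self.atlas is None:
            raise ValueError("an AtlasNetworks must be provided")
        self.roi_ids_ = self.atlas.roi_ids
        return self

    def transform(self, X) -> list[pd.DataFrame]:
        if not hasattr(self, "roi_ids_"):
            self.fit()
        out = []
        for item in X:
            if isinstance(item, RoiTimeSeries):
                ts = item
            else:
                arr = np.asarray(item, dtype=float).T  # to roi x time
                ts = RoiTimeSeries(matrix=arr, roi_ids=self.roi_ids_, tr=1.0)
            out.append(network_matrix(roi_fc_matrix(ts), self.atlas, self.scale))
        return out
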