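"""End-to-end orchestration: preprocessing -> VBM -> network FC -> clinical
correlation, plus report rendering.

A run is driven by a :class:`RunConfig` pointing at a cohort manifest (as
written by :func:`visionet.simulate.generate_cohort`, or assembled by hand
for compatible real data).  Subjects failing motion QC are dropped from
every downstream stage and listed in the report.  The run directory is
self-describing: config, seed and per-stage timings are written alongside
the outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as vio
from .datatypes import NETWORKS
from .netfc import (
    GroupFCComparison,
    compare_groups,
    correlate_clinical,
    extract_roi_timeseries,
    network_matrix,
    roi_fc_matrix,
)
from .preprocess import BandSpec, motion_qc, preprocess_bold
from .vbm import PermutationVBM, clusters_to_frame

__all__ = ["RunConfig", "run_pipeline", "render_report", "load_run_config"]


@dataclass
class RunConfig:
    """All stage parameters for one reproducible run.

    Defaults mirror the study recipe: discard 4 volumes, 2 mm / 2 degree
    motion exclusion, 0.01-0.08 Hz band, 6 mm FWHM smoothing for BOLD,
    3 mm sigma for gray-matter maps, TFCE E=0.5/H=2 with FWE alpha 0.0002,
    FC FDR alpha 0.05.
    """

    manifest: str = "manifest.json"
    out_dir: str = "visionet_run"
    n_discard: int = 4
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fwhm_mm: float = 6.0
    gm_smooth_sigma_mm: float = 3.0
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    connectivity: int = 26
    n_perm: int = 5000
    vbm_alpha: float = 0.0002
    fc_alpha: float = 0.05
    clinical_covariates: tuple[str, ...] = ("ammonia", "bilirubin")
    seed: int = 0
    run_vbm: bool = True
    run_netfc: bool = True
    run_clinical: bool = True

    def __post_init__(self) -> None:
        for a in (self.vbm_alpha, self.fc_alpha):
            if not 0 < a < 1:
                raise ValueError(f"alpha {a} outside (0, 1)")


def load_run_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "clinical_covariates" in raw:
        raw["clinical_covariates"] = tuple(raw["clinical_covariates"])
    return RunConfig(**raw)


def _qc_stage(manifest: dict, config: RunConfig, root: Path) -> tuple[pd.DataFrame, list[dict]]:
    rows, kept = [], []
    for subj in manifest["subjects"]:
        trace = vio.load_motion(root / subj["motion"])
        res = motion_qc(trace, config.max_translation_mm, config.max_rotation_deg)
        rows.append(
            {
                "subject_id": subj["id"],
                "group": subj["group"],
                "passed": res.passed,
                "max_translation_mm": res.max_translation_mm,
                "max_rotation_deg": res.max_rotation_deg,
                "n_offending_volumes": len(res.offending_volumes),
            }
        )
        if res.passed:
            kept.append(subj)
    return pd.DataFrame(rows), kept


def _netfc_stage(
    kept: list[dict], config: RunConfig, root: Path, atlas, tr: float
) -> tuple[GroupFCComparison, dict[str, pd.DataFrame]]:
    band = BandSpec(config.band_low_hz, config.band_high_hz)
    per_subject: dict[str, pd.DataFrame] = {}
    groups: dict[str, list[pd.DataFrame]] = {"patient": [], "control": []}
    for subj in kept:
        run = vio.load_bold(root / subj["bold"], tr=tr)
        run = preprocess_bold(run, config.n_discard, band, config.fwhm_mm)
        ts = extract_roi_timeseries(run, atlas)
        mat = network_matrix(roi_fc_matrix(ts), atlas)
        per_subject[subj["id"]] = mat
        groups[subj["group"]].append(mat)
    comparison = compare_groups(
        groups["patient"], groups["control"], alpha=config.fc_alpha
    )
    return comparison, per_subject


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and write the report bundle.

    Returns a results dict with the QC table, FC comparison, VBM clusters
    and clinical correlations; everything is also persisted under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = vio.load_manifest(config.manifest)
    root = Path(manifest["_root"])
    atlas = vio.load_atlas(root / manifest["atlas"], root / manifest["assignment"])
    tr = float(manifest.get("tr", 2.0))

    results: dict = {"excluded": []}
    timings: dict[str, float] = {}

    tic = time.perf_counter()
    qc_table, kept = _qc_stage(manifest, config, root)
    timings["motion_qc"] = time.perf_counter() - tic
    results["qc_table"] = qc_table
    results["excluded"] = qc_table.loc[~qc_table["passed"], "subject_id"].tolist()
    qc_table.to_csv(out / "motion_qc.tsv", sep="\t", index=False)

    if config.run_netfc:
        tic = time.perf_counter()
        comparison, per_subject = _netfc_stage(kept, config, root, atlas, tr)
        timings["netfc"] = time.perf_counter() - tic
        results["fc_comparison"] = comparison
        results["fc_per_subject"] = per_subject
        comparison.table.to_csv(out / "fc_comparison.tsv", sep="\t", index=False)
        comparison.patient_mean.to_csv(out / "fc_mean_patients.csv")
        comparison.control_mean.to_csv(out / "fc_mean_controls.csv")
        comparison.difference.to_csv(out / "fc_difference.csv")
        subj_rows = []
        for sid, mat in per_subject.items():
            row = {"subject_id": sid}
            for i, a in enumerate(NETWORKS):
                for j, b in enumerate(NETWORKS):
                    if j >= i:
                        row[f"{a}-{b}"] = mat.iloc[i, j]
            subj_rows.append(row)
        pd.DataFrame(subj_rows).to_csv(out / "fc_per_subject.tsv", sep="\t", index=False)

    if config.run_vbm:
        tic = time.perf_counter()
        maps, labels = [], []
        for subj in kept:
            maps.append(vio.load_gm_map(root / subj["gm"]))
            labels.append(0 if subj["group"] == "patient" else 1)  # control > patient
        voxel = float(np.abs(np.linalg.det(atlas.affine[:3, :3])) ** (1 / 3))
        vbm = PermutationVBM(
            E=config.tfce_E,
            H=config.tfce_H,
            connectivity=config.connectivity,
            n_perm=config.n_perm,
            alpha=config.vbm_alpha,
            smooth_sigma_mm=config.gm_smooth_sigma_mm,
            voxel_size_mm=voxel,
            random_state=config.seed,
        ).fit(maps, labels, affine=atlas.affine)
        timings["vbm"] = time.perf_counter() - tic
        results["vbm_clusters"] = vbm.clusters_
        results["vbm_pmap"] = vbm.pmap_
        clusters_to_frame(vbm.clusters_).to_csv(out / "vbm_clusters.tsv", sep="\t", index=False)

    if config.run_clinical and config.run_netfc and "clinical" in manifest:
        tic = time.perf_counter()
        clinical = pd.read_csv(root / manifest["clinical"], sep="\t")
        rows = []
        flagged = comparison.table.loc[comparison.table["significant"], "pair"].tolist()
        pairs = flagged or ["HVN-PVN"]
        pat_ids = [s["id"] for s in kept if s["group"] == "patient"]
        for pair in pairs:
            nets = pair.split("-") if "-" in pair else [pair, pair]
            fc_vals = np.array(
                [per_subject[sid].loc[nets[0], nets[1]] for sid in pat_ids]
            )
            sub = clinical.set_index("subject_id").loc[pat_ids]
            for cov in config.clinical_covariates:
                if cov not in sub:
                    continue
                ok = sub[cov].notna().to_numpy()
                if ok.sum() < 3:  # too few paired observations to correlate
                    continue
                res = correlate_clinical(fc_vals[ok], sub[cov].to_numpy()[ok])
                rows.append({"pair": pair, "covariate": cov, **res})
        results["clinical_correlations"] = pd.DataFrame(rows)
        timings["clinical"] = time.perf_counter() - tic
        if rows:
            results["clinical_correlations"].to_csv(
                out / "clinical_correlations.tsv", sep="\t", index=False
            )

    results["timings"] = timings
    (out / "run_log.json").write_text(
        json.dumps(
            {
                "config": asdict(config),
                "seed": config.seed,
                "excluded_subjects": results["excluded"],
                "timings": timings,
            },
            indent=2,
            default=str,
        )
    )
    render_report(results, out)
    return results


def render_report(results: dict, out_dir: str | Path) -> Path:
    """Write a human-readable markdown report plus figure files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# visionet run report", ""]

    if "qc_table" in results:
        excluded = results.get("excluded", [])
        lines += [
            "## Motion QC",
            "",
            f"Subjects excluded for head motion over threshold: "
            f"{', '.join(excluded) if excluded else 'none'}.",
            "",
        ]

    if "vbm_clusters" in results:
        clusters = results["vbm_clusters"]
        lines += ["## VBM clusters (FWE-corrected)", ""]
        if clusters:
            frame = clusters_to_frame(clusters)
            lines += [frame.to_markdown(index=False), ""]
        else:
            lines += ["No significant clusters at the configured threshold.", ""]

    comparison = results.get("fc_comparison")
    if comparison is not None:
        lines += [
            "## Network functional connectivity",
            "",
            comparison.table.to_markdown(index=False),
            "",
            "Group-mean matrices (Fisher-z scale) written as CSV: patients, "
            "controls, and their difference (patients minus controls).",
            "",
        ]
        _heatmaps(comparison, out)

    clin = results.get("clinical_correlations")
    if clin is not None and len(clin):
        lines += ["## Clinical correlation", "", clin.to_markdown(index=False), ""]

    if len(lines) <= 2:
        lines += ["No completed stages to report.", ""]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path


def _heatmaps(comparison: GroupFCComparison, out: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    mats = [
        (comparison.patient_mean, "Patients"),
        (comparison.control_mean, "Controls"),
        (comparison.difference, "Patients - Controls"),
    ]
    for ax, (mat, title) in zip(axes, mats):
        im = ax.imshow(mat.to_numpy(), cmap="coolwarm", vmin=-1, vmax=1)
        ax.set_xticks(range(3), mat.columns)
        ax.set_yticks(range(3), mat.index)
        ax.set_title(title)
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(out / "fc_matrices.png", dpi=120)
    plt.close(fig)
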