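"""Synthetic cohort generator.

Generates everything the analysis stages consume — BOLD runs with a known
network-level correlation structure, gray-matter density maps with an
optional injected group deficit, motion-parameter traces, clinical
covariate tables and the atlas that defines the three vision-related
networks (PVN, HVN, VSN) — so that every downstream stage can be tested
against ground truth without access to patient MRI data.

Model
-----
ROI mean signals for one subject are a draw from a zero-mean multivariate
normal whose correlation matrix is the ROI-level expansion of the 3x3
network target matrix: targets are specified on the Fisher-z scale and
mapped through tanh, every within-network ROI pair shares the network's
intra value and every cross-network pair the corresponding inter value.
Each in-brain voxel is its ROI signal plus white noise plus a slow
sinusoidal drift (two components with 128 s and 200 s periods, below the
0.01 Hz pass-band edge, so temporal filtering demonstrably removes them);
background voxels carry pure noise.  Drift phases are drawn per ROI —
spatially varying scanner drift — so drift cannot induce correlation
between distinct ROIs and the correlated-signal core alone carries the
target structure.

Determinism: every generator is a pure function of (config, seed).
Per-subject randomness comes from ``numpy.random.SeedSequence([master,
stream, subject_index])`` so changing the cohort size never reshuffles
existing subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MOTION_COLUMNS,
    NETWORKS,
    AtlasNetworks,
    Bold4D,
    GrayMatterMap,
    MotionTrace,
)

__all__ = [
    "SimConfig",
    "default_target_z",
    "expand_network_targets",
    "generate_atlas",
    "generate_bold",
    "generate_roi_signals",
    "generate_gm_maps",
    "generate_motion_trace",
    "generate_clinical_table",
    "generate_cohort",
]

# Group-mean network FC (Fisher-z scale) reported for the study cohorts,
# ordered (PVN, HVN, VSN): diagonal intra-FC, off-diagonal inter-FC.
_PATIENT_TARGET_Z = np.array(
    [
        [0.8102, 0.1108, 0.0294],
        [0.1108, 0.3950, 0.0499],
        [0.0294, 0.0499, 0.3092],
    ]
)
_CONTROL_TARGET_Z = np.array(
    [
        [0.9567, 0.3021, 0.0996],
        [0.3021, 0.4479, 0.1292],
        [0.0996, 0.1292, 0.3293],
    ]
)

# Clinical covariate moments (mean, sd) for the patient group; controls get
# age and sex only, the liver panel is not measured in healthy subjects.
_CLINICAL_MOMENTS = {
    "age_patient": (51.65, 11.25),
    "age_control": (51.00, 10.13),
    "ammonia": (51.60, 33.34),  # venous blood ammonia, umol/L
    "albumin": (34.30, 4.75),
    "bilirubin": (20.73, 9.84),
    "prothrombin_time": (38.78, 9.24),
}
_MALE_FRACTION = {"patient": 11 / 20, "control": 14 / 20}


def default_target_z(group: str) -> np.ndarray:
    """Study-condition 3x3 network z-FC targets for ``patient``/``control``."""
    if group == "patient":
        return _PATIENT_TARGET_Z.copy()
    if group == "control":
        return _CONTROL_TARGET_Z.copy()
    raise ValueError(f"unknown group {group!r}")


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort.

    Defaults reproduce the study's data structure: 20 subjects per group,
    240 volumes at TR = 2 s, 19 ROIs split 2/4/13 over PVN/HVN/VSN on a
    24x24x24 grid of 4 mm isotropic voxels.
    """

    n_per_group: int = 20
    n_volumes: int = 240
    tr: float = 2.0
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 4.0
    roi_count: int = 19
    network_sizes: tuple[int, int, int] = (2, 4, 13)  # PVN, HVN, VSN
    roi_block_size: int = 3  # ROI side length in voxels
    target_z_patient: np.ndarray = field(default_factory=lambda: _PATIENT_TARGET_Z.copy())
    target_z_control: np.ndarray = field(default_factory=lambda: _CONTROL_TARGET_Z.copy())
    drift_amplitude: float = 0.2
    noise_sd: float = 0.5
    gm_noise_sd: float = 0.1
    gm_effect_d: float = 1.5  # Cohen's d of the injected gray-matter deficit
    gm_effect_mask: np.ndarray | None = None  # default: PVN ROI voxels
    motion_spike_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 4:
            raise ValueError("n_volumes must exceed the 4 discarded volumes")
        if sum(self.network_sizes) != self.roi_count:
            raise ValueError(
                f"network_sizes {self.network_sizes} must sum to roi_count {self.roi_count}"
            )
        for z in (self.target_z_patient, self.target_z_control):
            z = np.asarray(z, dtype=float)
            if z.shape != (3, 3) or not np.allclose(z, z.T, atol=1e-12):
                raise ValueError("target_z must be a symmetric 3x3 matrix")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.motion_spike_prob <= 1:
            raise ValueError("motion_spike_prob must lie in [0, 1]")

    def target_z(self, group: str) -> np.ndarray:
        if group == "patient":
            return np.asarray(self.target_z_patient, dtype=float)
        if group == "control":
            return np.asarray(self.target_z_control, dtype=float)
        raise ValueError(f"unknown group {group!r}")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        # center the grid on the world origin
        aff[:3, 3] = -self.voxel_size_mm * (np.asarray(self.grid_shape) - 1) / 2.0
        return aff


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *map(int, stream)]))


# stream ids for seed splitting, so generators never share draws
_STREAM_BOLD = 1
_STREAM_GM = 2
_STREAM_MOTION = 3
_STREAM_CLINICAL = 4


def generate_atlas(config: SimConfig) -> AtlasNetworks:
    """Lay out ``roi_count`` disjoint cubic ROIs on the grid.

    Placement is deterministic (raster order with a one-voxel margin to the
    grid boundary) so the atlas depends only on the geometry fields of the
    config.
    """
    b = config.roi_block_size
    stride = b + 2  # >= one empty voxel between blocks and to the boundary
    starts = [np.arange(1, n - b, stride) for n in config.grid_shape]
    slots = [(x, y, z) for x in starts[0] for y in starts[1] for z in starts[2]]
    if len(slots) < config.roi_count:
        raise ValueError(
            f"grid {config.grid_shape} too small for {config.roi_count} "
            f"ROIs of side {b} (fits {len(slots)})"
        )
    labels = np.zeros(config.grid_shape, dtype=np.int16)
    for roi, (x, y, z) in enumerate(slots[: config.roi_count], start=1):
        labels[x : x + b, y : y + b, z : z + b] = roi
    assignment: dict[int, str] = {}
    roi = 1
    for net, size in zip(NETWORKS, config.network_sizes):
        for _ in range(size):
            assignment[roi] = net
            roi += 1
    return AtlasNetworks(labels=labels, assignment=assignment, affine=config.affine)


def expand_network_targets(
    target_z: np.ndarray,
    network_sizes: tuple[int, int, int],
    on_non_psd: str = "clip",
) -> np.ndarray:
    """ROI-level correlation matrix implied by 3x3 network z targets.

    Within-network ROI pairs share tanh(intra z), cross-network pairs
    tanh(inter z).  If the implied matrix is not positive semi-definite it
    is repaired by clipping negative eigenvalues at zero and rescaling the
    diagonal back to one (``on_non_psd="clip"``, with a warning), or
    rejected (``on_non_psd="raise"``).
    """
    target_z = np.asarray(target_z, dtype=float)
    if not np.all(np.isfinite(target_z)):
        raise ValueError("target_z entries must be finite")
    target_r = np.tanh(target_z)
    r = sum(network_sizes)
    corr = np.empty((r, r))
    bounds = np.cumsum([0, *network_sizes])
    for i in range(3):
        for j in range(3):
            corr[bounds[i] : bounds[i + 1], bounds[j] : bounds[j + 1]] = target_r[i, j]
    np.fill_diagonal(corr, 1.0)
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        bad = [
            (NETWORKS[i], NETWORKS[j], float(target_z[i, j]))
            for i in range(3)
            for j in range(i, 3)
        ]
        msg = (
            f"implied ROI correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals[0]:.4f}); network targets: {bad}"
        )
        if on_non_psd == "raise":
            raise ValueError(msg)
        warnings.warn(msg + " — clipping negative eigenvalues", RuntimeWarning)
        w, v = np.linalg.eigh(corr)
        corr = (v * np.clip(w, 0.0, None)) @ v.T
        d = np.sqrt(np.clip(np.diag(corr), 1e-12, None))
        corr = corr / np.outer(d, d)
    return corr


def _correlated_signals(
    corr: np.ndarray, n_volumes: int, rng: np.random.Generator
) -> np.ndarray:
    """(R, T) unit-variance Gaussian signals with population correlation ``corr``."""
    w, v = np.linalg.eigh(corr)
    chol = v * np.sqrt(np.clip(w, 0.0, None))
    return chol @ rng.standard_normal((corr.shape[0], n_volumes))


def _drift(config: SimConfig, rng: np.random.Generator, n_rois: int) -> np.ndarray:
    """(R, T) low-frequency drift, periods 128 s and 200 s, per-ROI phases."""
    t = np.arange(config.n_volumes) * config.tr
    phases = rng.uniform(0, 2 * np.pi, size=(n_rois, 2))
    return config.drift_amplitude * (
        np.sin(2 * np.pi * t / 128.0 + phases[:, :1])
        + np.sin(2 * np.pi * t / 200.0 + phases[:, 1:])
    )


def generate_roi_signals(
    group_target_z: np.ndarray,
    config: SimConfig,
    subject_seed: int,
    with_noise: bool = True,
    on_non_psd: str = "clip",
) -> np.ndarray:
    """(R, T) ROI-mean time series for one subject.

    This is the ROI-level shortcut of :func:`generate_bold`: the same
    correlated signals, with the white voxel noise already averaged down to
    ROI level (sd ``noise_sd / sqrt(voxels per ROI)``) and the same drift
    added, but without materializing a voxel grid.  Averaging the voxels of
    a run produced by :func:`generate_bold` with the same seed gives the
    same series up to the averaged-noise realization.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAM_BOLD, int(subject_seed)])
    )
    corr = expand_network_targets(group_target_z, config.network_sizes, on_non_psd)
    signals = _correlated_signals(corr, config.n_volumes, rng)
    drift = _drift(config, rng, corr.shape[0])
    if with_noise:
        n_vox = config.roi_block_size**3
        signals = signals + rng.standard_normal(signals.shape) * (
            config.noise_sd / np.sqrt(n_vox)
        )
    return signals + drift


def generate_bold(
    atlas: AtlasNetworks,
    group_target_z: np.ndarray,
    config: SimConfig,
    subject_seed: int,
    on_non_psd: str = "clip",
) -> Bold4D:
    """One subject's 4D BOLD run over the atlas grid.

    Every voxel of ROI i carries that ROI's signal plus independent white
    noise and the subject's drift; background voxels are pure noise.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAM_BOLD, int(subject_seed)])
    )
    corr = expand_network_targets(group_target_z, config.network_sizes, on_non_psd)
    signals = _correlated_signals(corr, config.n_volumes, rng)
    drift = _drift(config, rng, corr.shape[0])

    shape = atlas.labels.shape
    data = np.zeros((*shape, config.n_volumes), dtype=np.float32)
    labels = atlas.labels
    for roi in atlas.roi_ids:
        data[labels == roi] = signals[roi - 1] + drift[roi - 1]
    data += rng.standard_normal(data.shape).astype(np.float32) * config.noise_sd
    return Bold4D(data=data, affine=atlas.affine, tr=config.tr)


def _gm_template(shape: tuple[int, int, int]) -> np.ndarray:
    """Deterministic smooth base gray-matter density pattern in [0.2, 0.8]."""
    grids = np.meshgrid(*[np.linspace(0, np.pi, n) for n in shape], indexing="ij")
    return 0.2 + 0.6 * np.prod([np.sin(g) for g in grids], axis=0)


def generate_gm_maps(
    atlas: AtlasNetworks, config: SimConfig
) -> tuple[list[GrayMatterMap], list[GrayMatterMap]]:
    """(patients, controls) modulated gray-matter map sets.

    Controls: smooth base template + white subject noise (sd
    ``gm_noise_sd``).  Patients: identical except the mean inside
    ``gm_effect_mask`` is reduced by ``gm_effect_d * gm_noise_sd``,
    emulating a localized gray-matter deficit.  Default mask: the PVN ROI
    voxels.
    """
    shape = atlas.labels.shape
    mask = config.gm_effect_mask
    if mask is None:
        mask = np.isin(atlas.labels, atlas.rois_in("PVN"))
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("gm_effect_mask shape does not match the grid")
    if config.gm_effect_d != 0 and not mask.any():
        raise ValueError("gm_effect_mask is empty but gm_effect_d is nonzero")

    template = _gm_template(shape)
    deficit = config.gm_effect_d * config.gm_noise_sd

    def draw(group: str, idx: int) -> GrayMatterMap:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(config.seed), _STREAM_GM, 0 if group == "patient" else 1, idx]
            )
        )
        data = template + rng.standard_normal(shape) * config.gm_noise_sd
        if group == "patient":
            data = data - deficit * mask
        return GrayMatterMap(data=data, affine=atlas.affine)

    patients = [draw("patient", i) for i in range(config.n_per_group)]
    controls = [draw("control", i) for i in range(config.n_per_group)]
    return patients, controls


def generate_motion_trace(config: SimConfig, subject_seed: int) -> MotionTrace:
    """Six-column rigid-body motion trace (mm / degrees).

    A small-amplitude random walk clipped to |value| <= 1.5 so that clean
    traces always satisfy the 2 mm / 2 degree criterion; with probability
    ``motion_spike_prob`` one spike in (2.5, 4) magnitude is injected and
    the ground-truth QC label set to exclude.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAM_MOTION, int(subject_seed)])
    )
    steps = rng.normal(0.0, 0.02, size=(config.n_volumes, 6))
    walk = np.clip(np.cumsum(steps, axis=0), -1.5, 1.5)
    exclude = bool(rng.uniform() < config.motion_spike_prob)
    if exclude:
        vol = int(rng.integers(1, config.n_volumes))
        col = int(rng.integers(0, 6))
        walk[vol, col] = rng.uniform(2.5, 4.0) * rng.choice([-1.0, 1.0])
    table = pd.DataFrame(walk, columns=list(MOTION_COLUMNS))
    return MotionTrace(table=table, ground_truth_exclude=exclude)


def _censored_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, low: float = 0.0
) -> np.ndarray:
    """Normal draws censored at ``low``, like assay values below detection.

    Censoring (rather than rejection sampling) keeps the sample mean within
    ~1 unit of the nominal mean at this mean/sd ratio, so the generated
    cohort moments still match the published ones.
    """
    return np.maximum(rng.normal(mean, sd, size=size), low)


def generate_clinical_table(config: SimConfig) -> pd.DataFrame:
    """Per-subject clinical covariates with the study's group moments.

    Patients carry the liver panel (ammonia censored at zero, albumin,
    bilirubin, prothrombin time); controls have those fields missing, as in
    clinical practice where healthy subjects are not venipunctured for a
    liver panel.
    """
    if config.n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = _rng(config, _STREAM_CLINICAL)
    n = config.n_per_group
    rows = []
    for group in ("patient", "control"):
        mean, sd = _CLINICAL_MOMENTS[f"age_{group}"]
        ages = rng.normal(mean, sd, size=n)
        sexes = np.where(rng.uniform(size=n) < _MALE_FRACTION[group], "M", "F")
        if group == "patient":
            panel = {
                "ammonia": _censored_normal(rng, *_CLINICAL_MOMENTS["ammonia"], n),
                "albumin": rng.normal(*_CLINICAL_MOMENTS["albumin"], size=n),
                "bilirubin": rng.normal(*_CLINICAL_MOMENTS["bilirubin"], size=n),
                "prothrombin_time": rng.normal(
                    *_CLINICAL_MOMENTS["prothrombin_time"], size=n
                ),
            }
        else:
            panel = {
                k: np.full(n, np.nan)
                for k in ("ammonia", "albumin", "bilirubin", "prothrombin_time")
            }
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}_{i:03d}",
                    "group": group,
                    "age": ages[i],
                    "sex": sexes[i],
                    **{k: panel[k][i] for k in panel},
                }
            )
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig, out_dir: str | Path) -> dict:
    """Write a full cohort to disk and return its manifest.

    Produces per-subject BOLD runs (.nii.gz), gray-matter maps, motion TSVs,
    the atlas + network assignment table, the clinical table and a JSON
    manifest with ground-truth labels.
    """
    from . import io as vio  # local import: io depends on datatypes only

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = generate_atlas(config)
    vio.save_atlas(atlas, out / "atlas.nii.gz", out / "networks.tsv")
    clinical = generate_clinical_table(config)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    gm_patients, gm_controls = generate_gm_maps(atlas, config)

    subjects = []
    for g_idx, group in enumerate(("patient", "control")):
        gm_maps = gm_patients if group == "patient" else gm_controls
        for i in range(config.n_per_group):
            sid = f"{group}_{i:03d}"
            subject_seed = g_idx * config.n_per_group + i
            bold = generate_bold(atlas, config.target_z(group), config, subject_seed)
            motion = generate_motion_trace(config, subject_seed)
            bold_path = out / f"{sid}_bold.nii.gz"
            gm_path = out / f"{sid}_gm.nii.gz"
            motion_path = out / f"{sid}_motion.tsv"
            vio.save_bold(bold, bold_path)
            vio.save_gm_map(gm_maps[i], gm_path)
            motion.table.to_csv(motion_path, sep="\t", index=False)
            subjects.append(
                {
                    "id": sid,
                    "group": group,
                    "bold": bold_path.name,
                    "gm": gm_path.name,
                    "motion": motion_path.name,
                    "ground_truth": {"motion_exclude": motion.ground_truth_exclude},
                }
            )
    manifest = {
        "seed": int(config.seed),
        "tr": config.tr,
        "atlas": "atlas.nii.gz",
        "assignment": "networks.tsv",
        "clinical": "clinical.tsv",
        "subjects": subjects,
        "ground_truth": {
            "target_z_patient": np.asarray(config.target_z_patient).tolist(),
            "target_z_control": np.asarray(config.target_z_control).tolist(),
            "gm_effect_d": config.gm_effect_d,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def config_for_group(config: SimConfig, group: str) -> SimConfig:
    """Convenience: a copy of ``config`` whose both targets are ``group``'s."""
    z = config.target_z(group)
    return replace(config, target_z_patient=z.copy(), target_z_control=z.copy())
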