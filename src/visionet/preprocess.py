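"""Resting-state preprocessing: volume discarding, motion QC, temporal
band-pass filtering and spatial Gaussian smoothing.

The study's recipe is applied in the order discard -> motion QC ->
band-pass (0.01-0.08 Hz) -> smooth (6 mm FWHM).  Subjects whose motion
trace exceeds 2 mm translation or 2 degrees rotation at any volume are
excluded outright; "over" is read strictly, so a value of exactly 2.0
passes.

Two filter realizations are available.  The default is a zero-phase
FFT-domain ideal filter (frequency bins strictly outside [low, high] are
zeroed, which removes the DC component exactly); a 4th-order zero-phase
Butterworth is available for users who prefer smooth roll-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import Bold4D, MotionTrace

__all__ = [
    "BandSpec",
    "MotionQCResult",
    "discard_initial_volumes",
    "motion_qc",
    "bandpass",
    "bandpass_series",
    "smooth_gaussian",
    "fwhm_to_sigma",
    "TemporalBandpass",
    "GaussianSmoother",
    "preprocess_bold",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass(frozen=True)
class BandSpec:
    """Pass band in Hz; must sit below the Nyquist frequency 1/(2 TR)."""

    low_hz: float = 0.01
    high_hz: float = 0.08

    def validate(self, tr: float) -> None:
        nyquist = 1.0 / (2.0 * tr)
        if not 0 <= self.low_hz < self.high_hz < nyquist:
            raise ValueError(
                f"band [{self.low_hz}, {self.high_hz}] Hz infeasible for "
                f"TR={tr} s (Nyquist {nyquist:.4f} Hz)"
            )


@dataclass
class MotionQCResult:
    passed: bool
    offending_volumes: list[int]
    max_translation_mm: float
    max_rotation_deg: float


def discard_initial_volumes(run: Bold4D, n_discard: int = 4) -> Bold4D:
    """Drop the first ``n_discard`` volumes (magnetization equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= run.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {run.n_volumes} volumes"
        )
    return Bold4D(data=run.data[..., n_discard:], affine=run.affine, tr=run.tr)


def motion_qc(
    trace: MotionTrace,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> MotionQCResult:
    """Exclusion check: fail iff any |translation| > 2 mm or |rotation| > 2 deg.

    The thresholds are strict ("over"), so a volume at exactly the limit
    passes.  Offending volume indices are returned for reporting.
    """
    values = np.abs(trace.values)
    trans, rot = values[:, :3], values[:, 3:]
    bad = (trans > max_translation_mm).any(axis=1) | (rot > max_rotation_deg).any(axis=1)
    return MotionQCResult(
        passed=not bad.any(),
        offending_volumes=np.flatnonzero(bad).tolist(),
        max_translation_mm=float(trans.max()),
        max_rotation_deg=float(rot.max()),
    )


def _fft_bandpass(series: np.ndarray, tr: float, band: BandSpec) -> np.ndarray:
    """Zero-phase ideal filter along the last axis."""
    n = series.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _butter_bandpass(series: np.ndarray, tr: float, band: BandSpec) -> np.ndarray:
    nyquist = 1.0 / (2.0 * tr)
    low = max(band.low_hz, 1e-6) / nyquist
    sos = signal.butter(4, [low, band.high_hz / nyquist], btype="bandpass", output="sos")
    return signal.sosfiltfilt(sos, series - series.mean(axis=-1, keepdims=True), axis=-1)


def bandpass_series(
    series: np.ndarray,
    tr: float,
    band: BandSpec = BandSpec(),
    realization: str = "fft",
) -> np.ndarray:
    """Band-pass time series along the last axis (any leading shape)."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 16:
        raise ValueError("need at least 16 time points to band-pass")
    band.validate(tr)
    if realization == "fft":
        return _fft_bandpass(series, tr, band)
    if realization == "butterworth":
        return _butter_bandpass(series, tr, band)
    raise ValueError(f"unknown filter realization {realization!r}")


def bandpass(run: Bold4D, band: BandSpec = BandSpec(), realization: str = "fft") -> Bold4D:
    """Band-pass every voxel time series of a BOLD run."""
    filtered = bandpass_series(run.data.astype(float), run.tr, band, realization)
    return Bold4D(data=filtered, affine=run.affine, tr=run.tr)


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum."""
    return fwhm_mm * FWHM_TO_SIGMA


def smooth_gaussian(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 1.0
) -> np.ndarray:
    """Isotropic Gaussian smoothing; ``fwhm_mm = 0`` is the identity.

    Boundary handling is nearest-edge replication, so total intensity of an
    interior point source (kernel support away from the boundary) is
    conserved.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(volume, dtype=float), sigma_vox, mode="nearest")


class TemporalBandpass(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: band-pass (time x feature) arrays.

    ``transform`` accepts a single 2D array with time on the first axis
    (sklearn sample convention) or a list of them, and filters along time.
    Stateless; ``fit`` records the band actually used as ``band_``.
    """

    def __init__(
        self,
        low_hz: float = 0.01,
        high_hz: float = 0.08,
        tr: float = 2.0,
        realization: str = "fft",
    ):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.tr = tr
        self.realization = realization

    def fit(self, X=None, y=None) -> "TemporalBandpass":
        band = BandSpec(self.low_hz, self.high_hz)
        band.validate(self.tr)
        self.band_ = band
        return self

    def transform(self, X):
        if not hasattr(self, "band_"):
            self.fit()
        filt = lambda a: bandpass_series(
            np.asarray(a, dtype=float).T, self.tr, self.band_, self.realization
        ).T
        if isinstance(X, (list, tuple)):
            return [filt(x) for x in X]
        return filt(X)


class GaussianSmoother(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: isotropic Gaussian smoothing of 3D maps."""

    def __init__(self, fwhm_mm: float = 6.0, voxel_size_mm: float = 1.0):
        self.fwhm_mm = fwhm_mm
        self.voxel_size_mm = voxel_size_mm

    def fit(self, X=None, y=None) -> "GaussianSmoother":
        self.sigma_mm_ = fwhm_to_sigma(self.fwhm_mm)
        return self

    def transform(self, X):
        if isinstance(X, (list, tuple)):
            return [smooth_gaussian(x, self.fwhm_mm, self.voxel_size_mm) for x in X]
        return smooth_gaussian(X, self.fwhm_mm, self.voxel_size_mm)


def preprocess_bold(
    run: Bold4D,
    n_discard: int = 4,
    band: BandSpec = BandSpec(),
    fwhm_mm: float = 6.0,
    realization: str = "fft",
) -> Bold4D:
    """Discard initial volumes, band-pass, and spatially smooth one run."""
    run = discard_initial_volumes(run, n_discard)
    run = bandpass(run, band, realization)
    voxel = float(np.abs(np.linalg.det(run.affine[:3, :3])) ** (1.0 / 3.0))
    if fwhm_mm > 0:
        data = np.empty_like(run.data, dtype=float)
        for t in range(run.n_volumes):
            data[..., t] = smooth_gaussian(run.data[..., t], fwhm_mm, voxel)
        run = Bold4D(data=data, affine=run.affine, tr=run.tr)
    return run
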