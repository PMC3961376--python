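"""Per-voxel fluctuation-amplitude (coefficient of variation) maps.

The CV of a voxel is its temporal sample standard deviation (n-1
denominator) divided by the magnitude of its temporal mean — a
dimensionless, scale-invariant amplitude of the BOLD fluctuation.

Band-limited CV uses a zero-phase ideal (DFT-mask) band-pass on the
mean-removed series: frequency bins with ``low < f <= high`` are kept
(half-open so that adjacent bands partition the spectrum exactly, giving
an exact Parseval variance decomposition over any disjoint band partition
of (0, Nyquist]); DC is never included.  No padding or tapering is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import BoldSeries, TissueMask

logger = logging.getLogger(__name__)

__all__ = ["BandSpec", "CvMap", "cv_map", "bandpass_cv", "DEFAULT_BANDS"]

#: Relative floor (x in-mask median |mean|) below which a voxel's mean is
#: considered too small for a meaningful CV and the voxel is flagged invalid.
MEAN_FLOOR_REL = 1e-6


@dataclass(frozen=True)
class BandSpec:
    """A frequency band (Hz) with 0 < low < high."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValueError(
                f"band must satisfy 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )

    def __str__(self) -> str:
        return f"{self.low_hz:g}-{self.high_hz:g}Hz"


#: The three analysis bands: very-low, low, and the remainder up to 0.1 Hz.
DEFAULT_BANDS = (
    BandSpec(0.01, 0.014),
    BandSpec(0.014, 0.025),
    BandSpec(0.025, 0.1),
)


@dataclass
class CvMap:
    """Per-voxel CV, with validity flags and processing provenance.

    ``data`` is 0 wherever ``valid`` is False (out of mask or a mean too
    close to zero); downstream aggregators give such voxels zero weight.
    """

    data: np.ndarray
    valid: np.ndarray
    band_hz: tuple[float, float] | None = None
    provenance: list[str] = field(default_factory=list)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape or self.data.ndim != 3:
            raise ValueError("CV map and validity mask must be matching 3D arrays")
        inside = self.data[self.valid]
        if inside.size and not (np.isfinite(inside).all() and (inside >= 0).all()):
            raise ValueError("CV values must be finite and nonnegative where valid")


def _mean_and_valid(
    data: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal means plus the validity mask excluding near-zero means."""
    mean = data.mean(axis=-1)
    in_mask = np.abs(mean[mask])
    floor = MEAN_FLOOR_REL * np.median(in_mask)
    valid = mask & (np.abs(mean) > floor)
    n_dropped = int(mask.sum() - valid.sum())
    if n_dropped:
        logger.info("cv_map: %d in-mask voxels flagged invalid (near-zero mean)", n_dropped)
    return mean, valid


def cv_map(series: BoldSeries, brain_mask: TissueMask) -> CvMap:
    """Full-band CV: temporal sample std / |temporal mean| per in-mask voxel."""
    if brain_mask.data.shape != series.spatial_shape:
        raise ValueError("brain mask grid does not match the series")
    mask = brain_mask.data
    if not mask.any():
        raise ValueError("brain mask is empty")
    mean, valid = _mean_and_valid(series.data, mask)
    sd = series.data.std(axis=-1, ddof=1)
    cv = np.zeros(series.spatial_shape)
    cv[valid] = sd[valid] / np.abs(mean[valid])
    return CvMap(data=cv, valid=valid, band_hz=None, affine=series.affine.copy())


def _band_bins(freqs: np.ndarray, band: BandSpec, nyquist: float) -> np.ndarray:
    if band.high_hz > nyquist + 1e-12:
        raise ValueError(
            f"band {band} exceeds the Nyquist frequency {nyquist:.4g} Hz"
        )
    sel = (freqs > band.low_hz) & (freqs <= band.high_hz + 1e-15)
    sel[0] = False  # DC is never part of a fluctuation band
    return sel


def bandpass_cv(series: BoldSeries, band: BandSpec, brain_mask: TissueMask) -> CvMap:
    """Band-limited CV via a zero-phase DFT-mask filter on the fluctuation.

    The temporal mean is removed, frequency bins in (low, high] are kept,
    and the filtered fluctuation's sample std is divided by the original
    temporal mean.  An empty bin selection (band narrower than the spectral
    resolution) is an error.
    """
    if brain_mask.data.shape != series.spatial_shape:
        raise ValueError("brain mask grid does not match the series")
    mask = brain_mask.data
    if not mask.any():
        raise ValueError("brain mask is empty")
    T = series.n_timepoints
    nyq = 0.5 / series.tr_s
    freqs = np.fft.rfftfreq(T, d=series.tr_s)
    sel = _band_bins(freqs, band, nyq)
    if not sel.any():
        raise ValueError(
            f"band {band} contains no frequency bin at resolution "
            f"{freqs[1]:.4g} Hz"
        )
    mean, valid = _mean_and_valid(series.data, mask)

    flat = series.data.reshape(-1, T)
    idx = np.flatnonzero(valid.ravel())
    fluct = flat[idx] - flat[idx].mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(fluct, axis=1)
    spectrum[:, ~sel] = 0.0
    filtered = np.fft.irfft(spectrum, n=T, axis=1)
    sd = filtered.std(axis=1, ddof=1)

    cv = np.zeros(series.spatial_shape)
    cv.ravel()[idx] = sd / np.abs(mean.ravel()[idx])
    return CvMap(
        data=cv, valid=valid, band_hz=(band.low_hz, band.high_hz),
        affine=series.affine.copy(),
    )
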