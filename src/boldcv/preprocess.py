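"""Nuisance removal for BOLD series: motion regression, detrending, RETROICOR.

Every operation here is variance non-increasing per voxel and preserves the
voxel's temporal mean, so the downstream CV denominator (the temporal mean)
is unaffected by confound removal and the numerator can only shrink.

RETROICOR builds slice-specific low-order Fourier regressors in cardiac and
respiratory phase.  Cardiac phase is piecewise linear between detected
pulse peaks; respiratory phase uses histogram equalisation of the belt
amplitude with the sign of its derivative, so inspiration and expiration
map to opposite half-cycles.  The default model order is 2 (8 regressors:
cos/sin of 1x and 2x each phase).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, median_filter, minimum_filter1d, uniform_filter1d
from scipy.signal import find_peaks

from .io_formats import BoldSeries, MotionParams, PhysioTrace

logger = logging.getLogger(__name__)

__all__ = [
    "RegressorSet",
    "CardiacPeaks",
    "PeakDetectionError",
    "regress_confounds",
    "detrend_linear",
    "detect_cardiac_peaks",
    "cardiac_phase",
    "resp_phase",
    "retroicor_regressors",
    "motion_regressors",
    "mean_displacement",
]

#: Head radius (mm) converting rotation changes to displacement.
ROTATION_RADIUS_MM = 50.0

#: Minimum interval between successive cardiac peaks (240 bpm ceiling).
DEFAULT_REFRACTORY_S = 0.25

#: RETROICOR harmonic order (2 harmonics x 2 modalities x cos/sin = 8 columns).
RETROICOR_ORDER = 2


class PeakDetectionError(ValueError):
    """The cardiac trace yields too few usable peaks."""


@dataclass
class RegressorSet:
    """A nuisance design matrix, optionally one per slice.

    ``matrix`` is (T, k), or (n_slices, T, k) when ``slice_specific``.
    Columns may not be identically zero (a zero column indicates an
    upstream construction bug, not a removable confound).
    """

    matrix: np.ndarray
    labels: list[str]
    slice_specific: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        expected_ndim = 3 if self.slice_specific else 2
        if self.matrix.ndim != expected_ndim:
            raise ValueError(
                f"regressor matrix must be {expected_ndim}D "
                f"(slice_specific={self.slice_specific}), got {self.matrix.ndim}D"
            )
        k = self.matrix.shape[-1]
        if k < 1:
            raise ValueError("regressor set must have at least one column")
        if len(self.labels) != k:
            raise ValueError("one label required per regressor column")
        flat = self.matrix.reshape(-1, self.matrix.shape[-2], k)
        if (np.abs(flat).max(axis=(0, 1)) == 0).any():
            raise ValueError("regressor set contains an all-zero column")

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[-2]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[-1]


@dataclass
class CardiacPeaks:
    """Strictly increasing cardiac peak times (seconds, scan clock)."""

    peak_times_s: np.ndarray
    refractory_s: float = DEFAULT_REFRACTORY_S

    def __post_init__(self) -> None:
        self.peak_times_s = np.asarray(self.peak_times_s, dtype=float)
        if self.peak_times_s.ndim != 1 or self.peak_times_s.size < 2:
            raise ValueError("need at least two peak times")
        gaps = np.diff(self.peak_times_s)
        if (gaps <= 0).any():
            raise ValueError("peak times must be strictly increasing")
        if (gaps < self.refractory_s - 1e-9).any():
            raise ValueError(
                f"peak intervals violate the {self.refractory_s}s refractory period"
            )

    @property
    def rr_intervals_s(self) -> np.ndarray:
        return np.diff(self.peak_times_s)

    def mean_rate_hz(self) -> float:
        """Mean instantaneous cardiac frequency, mean of 1/RR."""
        return float(np.mean(1.0 / self.rr_intervals_s))


# ---------------------------------------------------------------------------
# Regression and detrending
# ---------------------------------------------------------------------------

def _residualize(y: np.ndarray, design: np.ndarray, labels: list[str]) -> np.ndarray:
    """Project out mean-centered regressors; y is (n_voxels, T).

    The design is centered, so the residual keeps each voxel's temporal
    mean, is orthogonal to every column, and the operation is an orthogonal
    projection (hence idempotent and variance non-increasing).  Linearly
    dependent columns are handled through the pseudoinverse and flagged.
    """
    xc = design - design.mean(axis=0, keepdims=True)
    keep = np.abs(xc).max(axis=0) > 0
    if not keep.all():
        dropped = [lbl for lbl, k in zip(labels, keep) if not k]
        warnings.warn(f"dropping constant regressor columns: {dropped}")
        xc = xc[:, keep]
        if xc.shape[1] == 0:
            return y
    rank = np.linalg.matrix_rank(xc)
    if rank < xc.shape[1]:
        warnings.warn(
            f"rank-deficient nuisance design (rank {rank} of {xc.shape[1]} "
            "columns); dependent columns contribute nothing extra"
        )
    beta = np.linalg.pinv(xc) @ y.T  # (k, n_voxels)
    return y - (xc @ beta).T


def regress_confounds(series: BoldSeries, regressors: RegressorSet) -> BoldSeries:
    """Remove nuisance regressors from every voxel by per-voxel OLS.

    The model per voxel is intercept + centered regressors; only the fitted
    regressor component is subtracted, so the temporal mean is preserved.
    All-zero voxels pass through unchanged (their projection is zero).
    """
    if regressors.n_timepoints != series.n_timepoints:
        raise ValueError(
            f"regressor rows ({regressors.n_timepoints}) != series length "
            f"({series.n_timepoints})"
        )
    data = series.data
    out = np.empty_like(data)
    if regressors.slice_specific:
        if regressors.matrix.shape[0] != series.n_slices:
            raise ValueError(
                "slice-specific regressors must have one design per slice"
            )
        mv = np.moveaxis(data, series.slice_axis, 0)
        ov = np.moveaxis(out, series.slice_axis, 0)
        for z in range(series.n_slices):
            y = mv[z].reshape(-1, series.n_timepoints)
            ov[z] = _residualize(y, regressors.matrix[z], regressors.labels).reshape(
                mv[z].shape
            )
    else:
        y = data.reshape(-1, series.n_timepoints)
        out = _residualize(y, regressors.matrix, regressors.labels).reshape(data.shape)
    return series.with_data(out)


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel first-order (linear) trend, preserving the mean.

    The least-squares slope against centered time is subtracted; the
    residual has exactly zero LS slope, so the operation is idempotent.
    """
    T = series.n_timepoints
    if T < 3:
        raise ValueError("linear detrending needs at least 3 timepoints")
    t = np.arange(T, dtype=float)
    tc = t - t.mean()
    y = series.data.reshape(-1, T)
    slope = (y @ tc) / (tc @ tc)
    out = y - slope[:, None] * tc[None, :]
    return series.with_data(out.reshape(series.data.shape))


# ---------------------------------------------------------------------------
# Cardiac peaks and physiological phases
# ---------------------------------------------------------------------------

def detect_cardiac_peaks(
    trace: np.ndarray | PhysioTrace,
    sample_hz: float | None = None,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    threshold_frac: float = 0.5,
    window_s: float = 2.0,
    smooth_s: float = 0.1,
    t0_offset_s: float | None = None,
) -> CardiacPeaks:
    """Detect pulse peaks with an adaptive rolling threshold.

    The trace is lightly smoothed (``smooth_s`` moving average, symmetric so
    peak positions are unbiased); the threshold at each sample is
    ``rolling_median + threshold_frac * (rolling_max - rolling_min)`` over a
    ``window_s`` window; candidate local maxima closer than the refractory
    period are suppressed.  Peak times are refined to sub-sample precision
    by parabolic interpolation.
    """
    if isinstance(trace, PhysioTrace):
        x = trace.cardiac
        sample_hz = trace.cardiac_hz
        t0 = trace.t0_offset_s if t0_offset_s is None else t0_offset_s
    else:
        if sample_hz is None:
            raise ValueError("sample_hz required for a bare array trace")
        x = np.asarray(trace, dtype=float)
        t0 = 0.0 if t0_offset_s is None else t0_offset_s

    if smooth_s > 0:
        x = uniform_filter1d(x, size=max(1, int(round(smooth_s * sample_hz)) | 1),
                             mode="nearest")
    w = max(3, int(round(window_s * sample_hz)) | 1)
    med = median_filter(x, size=w, mode="nearest")
    rng_ = maximum_filter1d(x, size=w, mode="nearest") - minimum_filter1d(
        x, size=w, mode="nearest"
    )
    threshold = med + threshold_frac * rng_
    idx, _ = find_peaks(x, height=threshold, distance=max(1, int(refractory_s * sample_hz)))
    if idx.size < 3:
        raise PeakDetectionError(
            f"only {idx.size} cardiac peaks detected; trace unusable"
        )
    # parabolic sub-sample refinement around each integer peak
    refined = idx.astype(float)
    interior = (idx > 0) & (idx < x.size - 1)
    i = idx[interior]
    denom = x[i - 1] - 2 * x[i] + x[i + 1]
    ok = denom < 0
    shift = np.zeros(i.size)
    shift[ok] = 0.5 * (x[i - 1] - x[i + 1])[ok] / denom[ok]
    refined[interior] += np.clip(shift, -0.5, 0.5)
    return CardiacPeaks(peak_times_s=t0 + refined / sample_hz,
                        refractory_s=refractory_s)


def cardiac_phase(peaks: CardiacPeaks, t: np.ndarray | float) -> np.ndarray:
    """Cardiac phase in [0, 2pi): linear from 0 at each peak to 2pi at the next.

    Times outside [first_peak, last_peak) are extrapolated with the nearest
    interval's rate and wrapped into [0, 2pi).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = peaks.peak_times_s
    k = np.clip(np.searchsorted(p, t, side="right") - 1, 0, p.size - 2)
    frac = (t - p[k]) / (p[k + 1] - p[k])
    return (2 * np.pi * frac) % (2 * np.pi)


def resp_phase(
    trace: np.ndarray | PhysioTrace,
    t: np.ndarray | float,
    sample_hz: float | None = None,
    n_bins: int = 100,
    smooth_s: float = 1.0,
    t0_offset_s: float | None = None,
) -> np.ndarray:
    """Respiratory phase in (-pi, pi] by amplitude histogram equalisation.

    ``phi(t) = pi * sign(dR/dt) * H(R(t))`` where ``H`` is the normalised
    cumulative amplitude histogram over the whole run (``n_bins`` bins) and
    the derivative comes from centered differences on the trace smoothed
    with a ``smooth_s`` moving average.
    """
    if isinstance(trace, PhysioTrace):
        x = trace.respiratory
        sample_hz = trace.respiratory_hz
        t0 = trace.t0_offset_s if t0_offset_s is None else t0_offset_s
    else:
        if sample_hz is None:
            raise ValueError("sample_hz required for a bare array trace")
        x = np.asarray(trace, dtype=float)
        t0 = 0.0 if t0_offset_s is None else t0_offset_s
    if np.ptp(x) == 0:
        raise ValueError("respiratory trace is constant; phase undefined")

    w = max(3, int(round(smooth_s * sample_hz)))
    xs = uniform_filter1d(x, size=w, mode="nearest")
    deriv = np.gradient(xs, 1.0 / sample_hz)

    lo, hi = xs.min(), xs.max()
    counts, edges = np.histogram(xs, bins=n_bins, range=(lo, hi))
    cum = np.concatenate([[0], np.cumsum(counts)]) / xs.size  # at bin edges

    t = np.atleast_1d(np.asarray(t, dtype=float))
    sample_t = t0 + np.arange(x.size) / sample_hz
    r_t = np.interp(t, sample_t, xs)
    d_t = np.interp(t, sample_t, deriv)
    bin_pos = np.clip((r_t - lo) / (hi - lo) * n_bins, 0, n_bins)
    h = np.interp(bin_pos, np.arange(n_bins + 1), cum)
    return np.pi * np.sign(d_t) * h


def retroicor_regressors(
    physio: PhysioTrace,
    n_timepoints: int,
    tr_s: float,
    slice_offsets_s: np.ndarray,
    order: int = RETROICOR_ORDER,
) -> RegressorSet:
    """Slice-specific Fourier regressors in cardiac and respiratory phase.

    For each slice and volume the cardiac and respiratory phases are
    evaluated at that slice's acquisition time; columns are cos/sin of
    m*phi for m = 1..order and both modalities (8 columns at order 2).
    """
    scan_end = tr_s * n_timepoints
    physio.check_covers(scan_end)
    peaks = detect_cardiac_peaks(physio)
    offsets = np.asarray(slice_offsets_s, dtype=float)
    t_slice = offsets[:, None] + np.arange(n_timepoints)[None, :] * tr_s

    phi_c = cardiac_phase(peaks, t_slice.ravel()).reshape(t_slice.shape)
    phi_r = resp_phase(physio, t_slice.ravel()).reshape(t_slice.shape)

    cols, labels = [], []
    for m in range(1, order + 1):
        for name, phi in (("cardiac", phi_c), ("resp", phi_r)):
            cols.append(np.cos(m * phi))
            labels.append(f"{name}_cos{m}")
            cols.append(np.sin(m * phi))
            labels.append(f"{name}_sin{m}")
    matrix = np.stack(cols, axis=-1)  # (n_slices, T, 2*2*order)
    return RegressorSet(matrix=matrix, labels=labels, slice_specific=True)


def motion_regressors(motion: MotionParams) -> RegressorSet:
    """The six rigid-body parameter time-courses as a nuisance design."""
    return RegressorSet(
        matrix=motion.params,
        labels=["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"],
        slice_specific=False,
    )


def mean_displacement(motion: MotionParams, radius_mm: float = ROTATION_RADIUS_MM) -> float:
    """Mean framewise displacement in mm.

    Per step: sum of absolute translation changes plus ``radius_mm`` times
    the sum of absolute rotation changes (rotations in radians); returns
    the mean over the T-1 steps.
    """
    d = np.diff(motion.params, axis=0)
    fd = np.abs(d[:, 3:]).sum(axis=1) + radius_mm * np.abs(d[:, :3]).sum(axis=1)
    return float(fd.mean())
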