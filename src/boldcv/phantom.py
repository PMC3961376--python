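"""Synthetic 4D BOLD phantom with ground-truth fluctuation amplitudes.

The phantom emulates a resting-state acquisition at the signal level (no
k-space or MR physics): a concentric-ellipsoid head with a gray-matter
shell, white-matter core and central ventricular CSF; per-voxel baseline
intensity; a band-limited power-law "spontaneous fluctuation" process whose
standard deviation is calibrated to a target coefficient of variation per
tissue; first-order scanner drift; quasi-periodic cardiac (photoplethysmograph
-like pulse train with RR jitter) and respiratory (amplitude-modulated
quasi-sinusoid) components sampled at each slice's acquisition time; and
white thermal noise.  Every random draw is governed by a single seed so an
identical spec reproduces an identical subject bit-for-bit.

The fluctuation process is generated by random-phase Fourier synthesis: bin
amplitudes follow the configured power law inside the passband and are zero
outside it, phases are uniform, and the realisation is rescaled so its
sample standard deviation (n-1 convention) equals the target exactly.  The
spectral confinement is therefore exact, and a downstream CV estimate
differs from truth only through the nuisance components and the pipeline
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import (
    TISSUES,
    BoldSeries,
    MotionParams,
    PhysioTrace,
    PveMap,
    TissueMask,
)

__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "InvalidSpecError",
    "build_geometry",
    "synth_physio",
    "synth_bold",
    "generate_subject",
    "write_subject",
]


class InvalidSpecError(ValueError):
    """The phantom specification is internally inconsistent."""


#: Baseline signal intensity per tissue (arbitrary units) used to build S0.
BASELINE_INTENSITY = {"GM": 1000.0, "WM": 950.0, "CSF": 750.0}

#: Intrinsic tissue CV levels (dimensionless) of the two emulated cohorts:
#: young healthy controls and elderly hypertensive CKD patients, at the
#: strict-threshold segmentation level.  CSF is not reported at the group
#: level; ~2x GM reflects the high fluctuation amplitude of ventricular CSF.
CONTROL_TISSUE_CV = {"GM": 4.6e-3, "WM": 3.0e-3, "CSF": 9.0e-3}
CKD_TISSUE_CV = {"GM": 7.9e-3, "WM": 4.2e-3, "CSF": 15.0e-3}

#: Group-level mean +/- SD of the strict-threshold tissue CVs (x1e-3 scale)
#: used when simulating subject-level values directly.
COHORT_CV_DISTRIBUTIONS = {
    ("control", "GM"): (4.6e-3, 0.6e-3),
    ("ckd", "GM"): (7.9e-3, 1.8e-3),
    ("control", "WM"): (3.0e-3, 0.4e-3),
    ("ckd", "WM"): (4.2e-3, 0.7e-3),
}

#: Sharpness of the synthetic photoplethysmograph pulse (von Mises kappa).
#: kappa = 2 keeps almost all pulse power in the first two cardiac
#: harmonics, matching the quasi-periodic model the correction assumes.
_PULSE_KAPPA = 2.0

#: Ellipsoid semi-axes of the three compartments, as fractions of the
#: half-grid.  Chosen so a 32^3 grid yields well over 2000 high-purity GM
#: voxels, the regime the aggregation statistics assume.
_BRAIN_FRAC = 0.45
_WM_FRAC = 0.28
_CSF_FRAC = 0.10


@dataclass
class PhantomSpec:
    """Full description of one synthetic subject.

    Defaults mirror the emulated acquisition: TR 2 s, 180 volumes,
    interleaved slices, cardiac ~1.13 Hz, and intrinsic tissue CVs at the
    young-healthy-control level (units are dimensionless CV, e.g. 4.6e-3).
    The test/desk default grid is 32^3.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (3.4, 3.4, 3.5)
    tr_s: float = 2.0
    n_timepoints: int = 180
    n_slices: int | None = None  # defaults to grid_shape[2]
    tissue_cv: dict[str, float] = field(
        default_factory=lambda: {"GM": 4.6e-3, "WM": 3.0e-3, "CSF": 9.0e-3}
    )
    fluct_band_hz: tuple[float, float] = (0.01, 0.1)
    spectral_exponent: float = -3.0
    drift_slope_frac_per_scan: float = 0.01
    cardiac_freq_hz: float = 1.13
    cardiac_jitter_frac: float = 0.05
    resp_freq_hz: float = 0.3
    physio_amp_frac: dict[str, float] = field(
        default_factory=lambda: {"GM": 2.0e-3, "WM": 1.0e-3, "CSF": 4.0e-3}
    )
    thermal_sd_frac: float = 5.0e-4
    physio_sample_hz: float = 100.0
    smooth_sigma_vox: float = 0.6
    motion_amp_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices is None:
            self.n_slices = self.grid_shape[2]
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise InvalidSpecError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise InvalidSpecError("voxel sizes must be positive")
        if not self.tr_s > 0:
            raise InvalidSpecError("tr_s must be positive")
        if self.n_timepoints < 2:
            raise InvalidSpecError("n_timepoints must be >= 2")
        if self.n_slices != self.grid_shape[2]:
            raise InvalidSpecError(
                "n_slices must equal the slice-axis extent grid_shape[2]"
            )
        for name, mapping in (("tissue_cv", self.tissue_cv),
                              ("physio_amp_frac", self.physio_amp_frac)):
            missing = set(TISSUES) - set(mapping)
            if missing:
                raise InvalidSpecError(f"{name} missing tissues {sorted(missing)}")
            if any(v < 0 for v in mapping.values()):
                raise InvalidSpecError(f"{name} values must be nonnegative")
        low, high = self.fluct_band_hz
        if not 0 < low < high:
            raise InvalidSpecError("fluct_band_hz must satisfy 0 < low < high")
        if high > self.nyquist_hz + 1e-12:
            raise InvalidSpecError(
                f"fluct_band_hz upper cutoff {high} exceeds Nyquist "
                f"{self.nyquist_hz:.4g} Hz"
            )
        if self.cardiac_freq_hz <= 0 or self.resp_freq_hz <= 0:
            raise InvalidSpecError("physiological frequencies must be positive")
        if self.cardiac_jitter_frac < 0 or self.thermal_sd_frac < 0:
            raise InvalidSpecError("jitter and noise fractions must be nonnegative")
        if self.physio_sample_hz < 10 * self.cardiac_freq_hz:
            raise InvalidSpecError(
                "physio_sample_hz must be at least 10x the cardiac frequency"
            )

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_s

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_timepoints


@dataclass
class PhantomSubject:
    """One generated subject: data, nuisance inputs, and generation truth."""

    bold: BoldSeries
    pve: dict[str, PveMap]
    brain_mask: TissueMask
    physio: PhysioTrace
    motion: MotionParams
    truth_cv: np.ndarray
    truth_cardiac_peaks_s: np.ndarray


def _ellipsoid_r2(shape: tuple[int, int, int], frac: float) -> np.ndarray:
    """Squared normalised ellipsoid radius per voxel (<=1 means inside)."""
    center = (np.asarray(shape) - 1) / 2.0
    semi = frac * (np.asarray(shape) - 1)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi):
        r2 += ((g - c) / a) ** 2
    return r2


def build_geometry(spec: PhantomSpec) -> dict[str, PveMap]:
    """Concentric-ellipsoid head model as fractional tissue maps.

    Hard labels (outer GM shell, WM core, central ventricular CSF) are
    smoothed with a Gaussian kernel of ``smooth_sigma_vox`` voxels and then
    renormalised so the three fractions sum to exactly 1 inside the brain
    envelope and are 0 outside; sigma 0 reproduces the binary labels.
    """
    if any(s < 16 for s in spec.grid_shape):
        raise InvalidSpecError(
            f"grid {spec.grid_shape} too small: each axis must be >= 16 to "
            "contain the three compartments"
        )
    shape = tuple(spec.grid_shape)
    brain = _ellipsoid_r2(shape, _BRAIN_FRAC) <= 1.0
    wm_region = _ellipsoid_r2(shape, _WM_FRAC) <= 1.0
    csf_region = _ellipsoid_r2(shape, _CSF_FRAC) <= 1.0
    labels = {
        "CSF": csf_region & brain,
        "WM": wm_region & ~csf_region & brain,
        "GM": brain & ~wm_region,
    }
    affine = np.diag((*spec.voxel_size_mm, 1.0))
    fractions = {}
    for tissue in TISSUES:
        frac = labels[tissue].astype(float)
        if spec.smooth_sigma_vox > 0:
            frac = gaussian_filter(frac, sigma=spec.smooth_sigma_vox)
        fractions[tissue] = frac
    total = sum(fractions.values())
    out = {}
    for tissue in TISSUES:
        frac = np.where(brain & (total > 0), fractions[tissue] / np.where(total > 0, total, 1.0), 0.0)
        out[tissue] = PveMap(data=np.clip(frac, 0.0, 1.0), tissue=tissue, affine=affine)
    return out


def brain_envelope(pve: dict[str, PveMap]) -> TissueMask:
    """Binary brain mask: voxels where the tissue fractions sum to ~1."""
    total = sum(p.data for p in pve.values())
    return TissueMask(data=total > 0.5, provenance="threshold",
                      affine=next(iter(pve.values())).affine)


# ---------------------------------------------------------------------------
# Physiology
# ---------------------------------------------------------------------------

def _cardiac_phase_from_peaks(peaks: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear cardiac phase (radians, unwrapped) at times t."""
    k = np.clip(np.searchsorted(peaks, t, side="right") - 1, 0, peaks.size - 2)
    frac = (t - peaks[k]) / (peaks[k + 1] - peaks[k])
    return 2 * np.pi * (k + frac)


def _pulse_waveform(phase: np.ndarray) -> np.ndarray:
    """Pulse-like periodic waveform of cardiac phase (peaks at phase 0 mod 2pi)."""
    return np.exp(_PULSE_KAPPA * (np.cos(phase) - 1.0))


def synth_physio(
    spec: PhantomSpec,
    rng: np.random.Generator | None = None,
    duration_s: float | None = None,
) -> tuple[PhysioTrace, np.ndarray]:
    """Generate cardiac and respiratory traces covering the scan.

    Returns the sampled traces plus the ground-truth cardiac peak times.
    RR intervals are drawn as ``(1/f_c) * (1 + jitter * z)`` with standard
    normal ``z`` (truncated to stay positive); the respiratory trace is a
    sinusoid at ``resp_freq_hz`` with ~10% slow amplitude modulation.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    duration = spec.duration_s if duration_s is None else duration_s
    pad = 3.0 / spec.cardiac_freq_hz
    mean_rr = 1.0 / spec.cardiac_freq_hz

    n_beats = int(np.ceil((duration + 2 * pad) * spec.cardiac_freq_hz * 1.5)) + 4
    rr = mean_rr * (1.0 + spec.cardiac_jitter_frac * rng.standard_normal(n_beats))
    rr = np.clip(rr, 0.3 * mean_rr, None)
    peaks = np.concatenate([[0.1 * mean_rr], 0.1 * mean_rr + np.cumsum(rr)])
    peaks = peaks[peaks <= duration + 2 * pad]

    n_samp = int(np.ceil((duration + pad) * spec.physio_sample_hz)) + 1
    t = np.arange(n_samp) / spec.physio_sample_hz
    cardiac = _pulse_waveform(_cardiac_phase_from_peaks(peaks, t))
    cardiac = (cardiac - cardiac.mean()) / cardiac.std(ddof=0)

    mod_phase = rng.uniform(0, 2 * np.pi)
    resp_phase0 = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.1 * np.sin(2 * np.pi * 0.015 * t + mod_phase)
    resp = envelope * np.sin(2 * np.pi * spec.resp_freq_hz * t + resp_phase0)
    resp = (resp - resp.mean()) / resp.std(ddof=0)

    trace = PhysioTrace(
        cardiac=cardiac, cardiac_hz=spec.physio_sample_hz,
        respiratory=resp, respiratory_hz=spec.physio_sample_hz,
        t0_offset_s=0.0,
    )
    return trace, peaks


# ---------------------------------------------------------------------------
# BOLD synthesis
# ---------------------------------------------------------------------------

def bandlimited_fluctuations(
    n_timepoints: int,
    tr_s: float,
    band_hz: tuple[float, float],
    spectral_exponent: float,
    rng: np.random.Generator,
    n_series: int = 1,
) -> np.ndarray:
    """Zero-mean band-limited noise with unit sample std (n-1), shape (n_series, T).

    Random-phase Fourier synthesis: deterministic power-law bin amplitudes
    ``f**(exponent/2)`` inside ``band_hz`` (half-open bins, Nyquist excluded),
    uniform random phases per series.  The realisation is exactly zero-mean
    and is rescaled to unit sample standard deviation, so the spectrum and
    the variance are both exact by construction.
    """
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_s)
    low, high = band_hz
    sel = (freqs > low - 1e-12) & (freqs <= high + 1e-12)
    sel[0] = False
    if n_timepoints % 2 == 0:
        sel[-1] = False  # Nyquist bin must be real; keep it out of the band
    if not sel.any():
        raise InvalidSpecError(
            f"band {band_hz} Hz contains no resolvable frequency bin at "
            f"TR={tr_s}s, T={n_timepoints}"
        )
    amp = np.zeros(freqs.size)
    amp[sel] = freqs[sel] ** (spectral_exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(n_series, freqs.size))
    spectrum = amp[None, :] * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n=n_timepoints, axis=1)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    return x / sd


def slice_offsets_interleaved(n_slices: int, tr_s: float) -> np.ndarray:
    """Even-spaced acquisition offsets in interleaved order (odd slices first... even)."""
    order = np.concatenate([np.arange(0, n_slices, 2), np.arange(1, n_slices, 2)])
    offsets = np.empty(n_slices)
    offsets[order] = np.arange(n_slices) * (tr_s / n_slices)
    return offsets


def _mix_by_pve(pve: dict[str, PveMap], per_tissue: dict[str, float]) -> np.ndarray:
    return sum(per_tissue[t] * pve[t].data for t in TISSUES)


def synth_bold(
    spec: PhantomSpec,
    pve: dict[str, PveMap],
    physio: PhysioTrace,
    truth_peaks_s: np.ndarray,
    rng: np.random.Generator | None = None,
) -> PhantomSubject:
    """Assemble the 4D series from fluctuation, drift, physio and noise.

    Per voxel i: ``S_i(t) = S0_i * (1 + cv_i*u_i(t) + d*t/T_scan + p_i(t))
    + eps_i(t)`` where ``u_i`` is unit-variance band-limited noise, ``p_i``
    is the cardiac+respiratory waveform evaluated at the voxel's slice
    acquisition time with PVE-mixed tissue amplitude, and ``eps`` is white
    thermal noise with sd ``thermal_sd_frac * S0_i``.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    shape = tuple(spec.grid_shape)
    T = spec.n_timepoints
    affine = next(iter(pve.values())).affine

    mask = brain_envelope(pve)
    s0 = _mix_by_pve(pve, BASELINE_INTENSITY) * mask.data
    truth_cv = _mix_by_pve(pve, spec.tissue_cv) * mask.data

    in_brain = mask.data
    idx = np.flatnonzero(in_brain)
    n_vox = idx.size

    signal = np.zeros(shape + (T,), dtype=float)
    flat = signal.reshape(-1, T)

    # intrinsic band-limited fluctuations, std calibrated to the mixed CV
    if any(v > 0 for v in spec.tissue_cv.values()):
        u = bandlimited_fluctuations(
            T, spec.tr_s, spec.fluct_band_hz, spec.spectral_exponent, rng, n_vox
        )
        flat[idx] += truth_cv.ravel()[idx, None] * u

    # first-order scanner drift, expressed as fraction of baseline per scan
    if spec.drift_slope_frac_per_scan != 0:
        t_frac = np.arange(T) / T
        flat[idx] += spec.drift_slope_frac_per_scan * t_frac[None, :]

    # cardiac + respiratory modulation at each slice's acquisition time
    offsets = slice_offsets_interleaved(spec.n_slices, spec.tr_s)
    if any(v > 0 for v in spec.physio_amp_frac.values()):
        amp = _mix_by_pve(pve, spec.physio_amp_frac) * in_brain
        t_slice = offsets[:, None] + np.arange(T)[None, :] * spec.tr_s  # (Z, T)
        card_t = physio.cardiac_times()
        resp_t = physio.respiratory_times()
        card_slice = np.interp(t_slice, card_t, physio.cardiac)
        resp_slice = np.interp(t_slice, resp_t, physio.respiratory)
        # split the tissue amplitude evenly (in variance) between modalities
        p = (card_slice + resp_slice) / np.sqrt(2.0)  # (Z, T)
        signal += amp[..., None] * p[None, None, :, :]

    series = s0[..., None] * (1.0 + signal)
    if spec.thermal_sd_frac > 0:
        series += (spec.thermal_sd_frac * s0)[..., None] * rng.standard_normal(
            s0.shape + (T,)
        )

    bold = BoldSeries(
        data=series, tr_s=spec.tr_s, slice_axis=2,
        slice_offsets_s=offsets, affine=affine,
    )

    motion = _synth_motion(spec, rng)
    return PhantomSubject(
        bold=bold, pve=pve, brain_mask=mask, physio=physio, motion=motion,
        truth_cv=truth_cv, truth_cardiac_peaks_s=np.asarray(truth_peaks_s),
    )


def _synth_motion(spec: PhantomSpec, rng: np.random.Generator) -> MotionParams:
    """Zero motion by default; optionally a small rigid drift plus tremor.

    ``motion_amp_mm`` sets the end-of-scan translation drift; rotations use
    the same amplitude divided by a 50 mm head radius.  A little white
    tremor keeps the six columns linearly independent so regression is
    genuinely exercised.
    """
    T = spec.n_timepoints
    params = np.zeros((T, 6))
    if spec.motion_amp_mm > 0:
        ramp = np.linspace(0.0, 1.0, T)
        direction = rng.standard_normal(6)
        direction /= np.abs(direction).max()
        scale = np.array([spec.motion_amp_mm / 50.0] * 3 + [spec.motion_amp_mm] * 3)
        params = ramp[:, None] * direction[None, :] * scale[None, :]
        params += 0.05 * scale[None, :] * rng.standard_normal((T, 6))
    return MotionParams(params=params)


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Generate one complete subject from a spec; fully seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    pve = build_geometry(spec)
    physio, peaks = synth_physio(spec, rng)
    return synth_bold(spec, pve, physio, peaks, rng)


def generate_cohort(spec: PhantomSpec, n_subjects: int) -> list[PhantomSubject]:
    """Generate ``n_subjects`` independent subjects, seeds ``seed .. seed+n-1``."""
    return [
        generate_subject(replace(spec, seed=spec.seed + i)) for i in range(n_subjects)
    ]


def write_subject(subject: PhantomSubject, out_dir, prefix: str = "sub") -> dict[str, str]:
    """Write all artifacts of one subject to a directory; returns the path map."""
    from pathlib import Path

    from . import io_formats as iof

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": out / f"{prefix}_bold.nii.gz",
        "brain_mask": out / f"{prefix}_brainmask.nii.gz",
        "truth_cv": out / f"{prefix}_truthcv.nii.gz",
        "cardiac": out / f"{prefix}_cardiac.tsv",
        "resp": out / f"{prefix}_resp.tsv",
        "motion": out / f"{prefix}_motion.par",
    }
    iof.write_bold(subject.bold, paths["bold"])
    iof.write_mask(subject.brain_mask, paths["brain_mask"])
    iof.write_scalar_map(subject.truth_cv, subject.bold.affine, paths["truth_cv"])
    iof.write_physio(subject.physio, paths["cardiac"], paths["resp"])
    iof.write_motion(subject.motion, paths["motion"])
    for tissue, pve in subject.pve.items():
        p = out / f"{prefix}_pve_{tissue.lower()}.nii.gz"
        iof.write_pve(pve, p)
        paths[f"pve_{tissue}"] = p
    return {k: str(v) for k, v in paths.items()}
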