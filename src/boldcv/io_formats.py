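"""On-disk formats and in-memory containers for the CV-mapping pipeline.

All images are NIfTI-1 (``.nii``/``.nii.gz``) read and written through
nibabel; physiological traces are 2-column TSV (``time_s``, ``amplitude``);
motion parameters are plain whitespace-delimited 6-column text (three
rotations in radians followed by three translations in mm, one row per
volume — the common realignment-output convention); results tables are TSV.

Every reader validates its input and raises :class:`FormatError` on
silently-corrupting content (non-finite voxels, negative partial-volume
fractions, non-monotone physio timestamps) rather than propagating it.
All images in one analysis must share a voxel grid; no resampling is done
here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("GM", "WM", "CSF")

#: Default uniform rate (Hz) physio traces are resampled to when their
#: timestamps are uneven.  Phase interpolation needs a uniform grid.
DEFAULT_PHYSIO_HZ = 100.0


class FormatError(ValueError):
    """An on-disk artifact violates the package's format contract."""


def _check_affine(affine) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise FormatError(f"affine must be 4x4, got {affine.shape}")
    return affine


@dataclass
class BoldSeries:
    """A 4D BOLD time series with acquisition timing metadata.

    Parameters
    ----------
    data
        4D array, spatial axes first, time last (arbitrary signal units).
    tr_s
        Repetition time in seconds (volume sampling interval).
    slice_axis
        Spatial axis that indexes slices (default 2, axial).
    slice_offsets_s
        Per-slice acquisition offset within the TR, seconds in ``[0, tr_s)``.
        ``None`` means all-zero offsets (no slice timing information).
    affine
        4x4 voxel-to-world transform.
    """

    data: np.ndarray
    tr_s: float
    slice_axis: int = 2
    slice_offsets_s: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"BOLD series must be 4D, got {self.data.ndim}D")
        if self.data.shape[-1] < 2:
            raise FormatError("BOLD series needs at least 2 timepoints")
        if not np.isfinite(self.data).all():
            raise FormatError("BOLD series contains non-finite voxels")
        if not (self.tr_s > 0):
            raise FormatError(f"TR must be positive, got {self.tr_s}")
        if not 0 <= self.slice_axis <= 2:
            raise FormatError("slice_axis must be a spatial axis (0, 1 or 2)")
        if self.slice_offsets_s is None:
            self.slice_offsets_s = np.zeros(self.n_slices)
        self.slice_offsets_s = np.asarray(self.slice_offsets_s, dtype=float)
        if self.slice_offsets_s.shape != (self.n_slices,):
            raise FormatError(
                f"need one slice offset per slice ({self.n_slices}), "
                f"got shape {self.slice_offsets_s.shape}"
            )
        if ((self.slice_offsets_s < 0) | (self.slice_offsets_s >= self.tr_s)).any():
            raise FormatError("slice offsets must lie in [0, TR)")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def n_slices(self) -> int:
        return self.data.shape[self.slice_axis]

    @property
    def duration_s(self) -> float:
        return self.tr_s * self.n_timepoints

    def frame_times(self) -> np.ndarray:
        """Nominal start time of each volume (seconds from scan start)."""
        return np.arange(self.n_timepoints) * self.tr_s

    def slice_times(self) -> np.ndarray:
        """Acquisition time of every (slice, volume), shape (n_slices, T)."""
        return self.slice_offsets_s[:, None] + self.frame_times()[None, :]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Copy of this series with a replacement data array."""
        return BoldSeries(
            data=data,
            tr_s=self.tr_s,
            slice_axis=self.slice_axis,
            slice_offsets_s=self.slice_offsets_s.copy(),
            affine=self.affine.copy(),
        )


@dataclass
class PveMap:
    """Per-voxel partial-volume fraction of one tissue class, in [0, 1]."""

    data: np.ndarray
    tissue: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"PVE map must be 3D, got {self.data.ndim}D")
        if not np.isfinite(self.data).all():
            raise FormatError("PVE map contains non-finite values")
        if (self.data < 0).any() or (self.data > 1).any():
            raise FormatError("PVE fractions must lie in [0, 1]")
        if self.tissue not in TISSUES:
            raise FormatError(f"unknown tissue label {self.tissue!r}")
        self.affine = _check_affine(self.affine)


@dataclass
class TissueMask:
    """Binary region mask (thresholded PVE, standard template, or drawn ROI)."""

    data: np.ndarray
    provenance: str = "threshold"  # threshold | template | manual_roi
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise FormatError(f"mask must be 3D, got {arr.ndim}D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise FormatError("mask is not strictly binary")
        self.data = arr.astype(bool)
        if self.provenance not in ("threshold", "template", "manual_roi"):
            raise FormatError(f"unknown mask provenance {self.provenance!r}")
        self.affine = _check_affine(self.affine)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class PhysioTrace:
    """Uniformly sampled cardiac and respiratory waveforms.

    ``t0_offset_s`` is the time of the first trace sample relative to the
    first BOLD volume (negative if recording started before the scan).
    """

    cardiac: np.ndarray
    cardiac_hz: float
    respiratory: np.ndarray
    respiratory_hz: float
    t0_offset_s: float = 0.0

    def __post_init__(self) -> None:
        self.cardiac = np.asarray(self.cardiac, dtype=float)
        self.respiratory = np.asarray(self.respiratory, dtype=float)
        for name, arr, hz in (
            ("cardiac", self.cardiac, self.cardiac_hz),
            ("respiratory", self.respiratory, self.respiratory_hz),
        ):
            if arr.ndim != 1 or arr.size < 2:
                raise FormatError(f"{name} trace must be a 1D series")
            if not np.isfinite(arr).all():
                raise FormatError(f"{name} trace contains non-finite samples")
            if not hz > 0:
                raise FormatError(f"{name} sample rate must be positive")

    def cardiac_times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.cardiac.size) / self.cardiac_hz

    def respiratory_times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.respiratory.size) / self.respiratory_hz

    def duration_s(self) -> float:
        """Duration jointly covered by both traces, from ``t0_offset_s``."""
        return min(
            (self.cardiac.size - 1) / self.cardiac_hz,
            (self.respiratory.size - 1) / self.respiratory_hz,
        )

    def check_covers(self, scan_end_s: float) -> None:
        """Raise if either trace ends before ``scan_end_s`` (scan clock)."""
        end = self.t0_offset_s + self.duration_s()
        if self.t0_offset_s > 0 or end < scan_end_s:
            raise FormatError(
                f"physio traces cover [{self.t0_offset_s:.2f}, {end:.2f}] s "
                f"but the scan spans [0, {scan_end_s:.2f}] s"
            )


@dataclass
class MotionParams:
    """Rigid-body realignment parameters: (T, 6) = 3 rotations rad, 3 translations mm."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise FormatError(
                f"motion parameters must be (T, 6), got {self.params.shape}"
            )
        if self.params.shape[0] < 2:
            raise FormatError("motion parameters need at least 2 timepoints")
        if not np.isfinite(self.params).all():
            raise FormatError("motion parameters contain non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.params.shape[0]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, 3:]


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------

def read_bold(
    path: str | Path,
    tr_s: float | None = None,
    slice_offsets_s: np.ndarray | None = None,
    slice_axis: int = 2,
) -> BoldSeries:
    """Read a 4D NIfTI BOLD series.

    TR is taken from the header's 4th zoom unless ``tr_s`` overrides it; a
    header TR of zero with no override is an error.  Missing slice timing
    defaults to all-zero offsets with a logged warning (RETROICOR phases are
    then evaluated at nominal volume times).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {data.ndim}D")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) >= 4 else 0.0
        if tr_s <= 0:
            raise FormatError(
                f"{path}: header TR is {tr_s}; pass an explicit TR override"
            )
    if slice_offsets_s is None:
        logger.warning("%s: no slice timing given; assuming all-zero offsets", path)
    return BoldSeries(
        data=data,
        tr_s=float(tr_s),
        slice_axis=slice_axis,
        slice_offsets_s=slice_offsets_s,
        affine=img.affine,
    )


def write_bold(series: BoldSeries, path: str | Path) -> None:
    img = nib.Nifti1Image(series.data, series.affine)
    zooms = np.abs(np.diag(series.affine)[:3])
    zooms[zooms == 0] = 1.0
    img.header.set_zooms((*zooms, series.tr_s))
    nib.save(img, str(path))


def read_pve(path: str | Path, tissue: str) -> PveMap:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: PVE map must be 3D, got {data.ndim}D")
    return PveMap(data=data, tissue=tissue, affine=img.affine)


def write_pve(pve: PveMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(pve.data, pve.affine), str(path))


def read_mask(path: str | Path, provenance: str = "threshold") -> TissueMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: mask must be 3D, got {data.ndim}D")
    return TissueMask(data=data, provenance=provenance, affine=img.affine)


def write_mask(mask: TissueMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))


def read_scalar_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D scalar NIfTI (e.g. a CV map); returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise FormatError(f"{path}: scalar map must be 3D, got {data.ndim}D")
    return data, img.affine


def write_scalar_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=float), affine), str(path))


# ---------------------------------------------------------------------------
# Physio TSV
# ---------------------------------------------------------------------------

def _read_physio_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise FormatError(f"{path}: empty physio file")
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise FormatError(f"{path}: physio TSV needs columns time_s, amplitude")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["amplitude"].to_numpy(dtype=float)
    if not (np.isfinite(t).all() and np.isfinite(x).all()):
        raise FormatError(f"{path}: non-finite physio samples")
    if t.size < 2:
        raise FormatError(f"{path}: physio trace needs at least 2 samples")
    if (np.diff(t) <= 0).any():
        raise FormatError(f"{path}: physio time column is not strictly increasing")
    return t, x


def _to_uniform(t: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Resample (t, x) onto a uniform grid by linear interpolation.

    Already-uniform inputs pass through unchanged.  The uniform rate is the
    reciprocal of the median timestep, so a few dropped samples do not alter
    the nominal rate.
    """
    dt = np.diff(t)
    if np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        return x, 1.0 / dt[0], t[0]
    rate = 1.0 / float(np.median(dt))
    n = int(round((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return np.interp(grid, t, x), rate, t[0]


def read_physio(cardiac_path: str | Path, resp_path: str | Path) -> PhysioTrace:
    """Read cardiac and respiratory TSV traces into a uniform-rate pair.

    Both files must start at the same time origin (scan-relative seconds);
    the earlier of the two starts defines ``t0_offset_s``.
    """
    tc, xc = _read_physio_column(cardiac_path)
    tr, xr = _read_physio_column(resp_path)
    xc, fc, t0c = _to_uniform(tc, xc)
    xr, fr, t0r = _to_uniform(tr, xr)
    if abs(t0c - t0r) > 1.0 / min(fc, fr):
        raise FormatError(
            f"cardiac and respiratory traces start at different times "
            f"({t0c:.3f} vs {t0r:.3f} s)"
        )
    return PhysioTrace(
        cardiac=xc, cardiac_hz=fc, respiratory=xr, respiratory_hz=fr,
        t0_offset_s=float(min(t0c, t0r)),
    )


def write_physio(trace: PhysioTrace, cardiac_path: str | Path, resp_path: str | Path) -> None:
    for path, t, x in (
        (cardiac_path, trace.cardiac_times(), trace.cardiac),
        (resp_path, trace.respiratory_times(), trace.respiratory),
    ):
        pd.DataFrame({"time_s": t, "amplitude": x}).to_csv(
            path, sep="\t", index=False, float_format="%.9g"
        )


# ---------------------------------------------------------------------------
# Motion parameters and results tables
# ---------------------------------------------------------------------------

def read_motion(path: str | Path) -> MotionParams:
    try:
        arr = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: unreadable motion-parameter file: {exc}") from exc
    if arr.size == 0:
        raise FormatError(f"{path}: empty motion-parameter file")
    if arr.shape[1] != 6:
        raise FormatError(
            f"{path}: motion file must have 6 columns, got {arr.shape[1]}"
        )
    return MotionParams(params=arr)


def write_motion(motion: MotionParams, path: str | Path) -> None:
    np.savetxt(str(path), motion.params, fmt="%.12g")


#: Column order of the per-subject results table.
TABLE_COLUMNS = ["subject", "group", "tissue", "method", "band", "cv", "n"]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV, 12 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
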