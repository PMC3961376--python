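"""Reduce a CV map to per-tissue scalars.

Three aggregation strategies, matching the three segmentation approaches
the analysis is designed around:

* **pve** — partial-volume-weighted mean, ``sum(PVE_i * CV_i) / sum(PVE_i)``
  over valid brain voxels;
* **strict** — plain mean over voxels whose tissue fraction strictly
  exceeds a threshold (default 0.8);
* **template** — plain mean over a supplied binary mask (standard-template
  GM/WM masks, or a manually drawn ROI such as the periventricular region).

Voxels flagged invalid in the CV map (near-zero mean) carry zero weight in
every aggregator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .fluctuation import CvMap
from .io_formats import PveMap, TissueMask

logger = logging.getLogger(__name__)

__all__ = ["TissueCv", "pve_weighted_mean", "strict_threshold_mean", "template_mean"]

#: Voxel count below which a strict-threshold mask is flagged as possibly
#: too small for a stable tissue mean.
ADEQUATE_VOXEL_COUNT = 2000


class EmptyRegionError(ValueError):
    """No voxel (or weight) survives the aggregation criterion."""


@dataclass
class TissueCv:
    """One aggregated CV value: subject x tissue x method (x band)."""

    subject_id: str
    tissue: str  # GM | WM | ROI
    method: str  # pve | strict | template | roi
    value: float
    n: float  # voxel count, or sum of PVE weights
    band_hz: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.value >= 0:
            raise ValueError(f"aggregated CV must be nonnegative, got {self.value}")
        if not self.n > 0:
            raise ValueError("effective sample size must be positive")

    @property
    def band_label(self) -> str:
        if self.band_hz is None:
            return "full"
        return f"{self.band_hz[0]:g}-{self.band_hz[1]:g}Hz"


def _check_grids(cv: CvMap, other_shape: tuple[int, ...], what: str) -> None:
    if cv.data.shape != other_shape:
        raise ValueError(f"{what} grid {other_shape} does not match CV map {cv.data.shape}")


def pve_weighted_mean(cv: CvMap, pve: PveMap, subject_id: str = "") -> TissueCv:
    """Partial-volume-weighted mean CV for one tissue.

    ``value = sum_i PVE_i * CV_i / sum_i PVE_i`` over valid brain voxels;
    the recorded effective n is the sum of the weights.
    """
    _check_grids(cv, pve.data.shape, "PVE map")
    w = pve.data * cv.valid
    wsum = w.sum()
    if wsum <= 0:
        raise EmptyRegionError(f"no {pve.tissue} partial volume inside the valid mask")
    value = float((w * cv.data).sum() / wsum)
    return TissueCv(subject_id=subject_id, tissue=pve.tissue, method="pve",
                    value=value, n=float(wsum), band_hz=cv.band_hz)


def strict_threshold_mean(
    cv: CvMap, pve: PveMap, threshold: float = 0.8, subject_id: str = ""
) -> TissueCv:
    """Mean CV over voxels whose tissue fraction strictly exceeds ``threshold``.

    The inequality is strict: a voxel at exactly the threshold is excluded.
    A warning is logged when fewer voxels survive than the count regarded
    as adequate for a stable mean.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    _check_grids(cv, pve.data.shape, "PVE map")
    sel = (pve.data > threshold) & cv.valid
    count = int(sel.sum())
    if count == 0:
        raise EmptyRegionError(
            f"no {pve.tissue} voxel exceeds PVE threshold {threshold}"
        )
    if count < ADEQUATE_VOXEL_COUNT:
        logger.warning(
            "strict-threshold %s mask has only %d voxels (<%d); tissue mean "
            "may be unstable", pve.tissue, count, ADEQUATE_VOXEL_COUNT,
        )
    return TissueCv(subject_id=subject_id, tissue=pve.tissue, method="strict",
                    value=float(cv.data[sel].mean()), n=float(count),
                    band_hz=cv.band_hz)


def template_mean(
    cv: CvMap, mask: TissueMask, tissue: str, subject_id: str = "", method: str = "template"
) -> TissueCv:
    """Mean CV over a binary mask (template segmentation or a drawn ROI)."""
    _check_grids(cv, mask.data.shape, "mask")
    sel = mask.data & cv.valid
    count = int(sel.sum())
    if count == 0:
        raise EmptyRegionError(f"{method} mask for {tissue} is empty")
    return TissueCv(subject_id=subject_id, tissue=tissue, method=method,
                    value=float(cv.data[sel].mean()), n=float(count),
                    band_hz=cv.band_hz)
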