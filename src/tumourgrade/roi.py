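"""Automated square-ROI sampling of tumour parameter maps.

Mirrors the clinical measurement protocol: a fixed-area square ROI (default
50 mm²) is slid over every axial-slice position at which it fits wholly
inside the tumour mask; the placement with the lowest mean ADC defines
ADC_ROI-mean / ADC_ROI-min, and the placement with the highest mean CBF
defines CBF_ROI-max (the maximum voxel within that ROI).  CBF is normalised
to the mean grey-matter CBF on the axial slice at the tumour's mid-point
(tumour voxels excluded), giving nCBF_ROI-max.  Whole-tumour statistics and
an ROI-size sweep (25/50/75/100 mm²) support sensitivity analyses.

ROIs are planar (single axial slice), matching placement on axial images;
tie-breaks follow scan order (slice, then row, then column), so all outputs
are deterministic.  Placements containing non-finite voxels are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .quant import VolumeGrid, _require_aligned

log = logging.getLogger(__name__)

DEFAULT_AREAS = (25.0, 50.0, 75.0, 100.0)


class NoPlacementError(ValueError):
    """No position of the requested footprint fits inside the mask."""


class EmptyReferenceError(ValueError):
    """No eligible grey-matter voxels on the tumour mid-slice."""


@dataclass(frozen=True)
class SquareROI:
    """A square ROI on one axial slice, in 0-based voxel indices."""

    slice: int
    row0: int
    col0: int
    h_vox: int
    w_vox: int
    nominal_area: float  # mm^2

    def voxel_block(self) -> tuple[slice, slice, int]:
        return (slice(self.row0, self.row0 + self.h_vox),
                slice(self.col0, self.col0 + self.w_vox),
                self.slice)


@dataclass
class TumourMeasurements:
    """The five ROI-derived biomarkers plus whole-tumour statistics."""

    adc_roi_mean: float | None = None
    adc_roi_min: float | None = None
    cbf_roi_max: float | None = None
    cbf_gm: float | None = None
    ncbf_roi_max: float | None = None
    adc_roi: SquareROI | None = None
    cbf_roi: SquareROI | None = None
    whole_tumour: dict = field(default_factory=dict)
    roi_area: float = 50.0
    flags: list[str] = field(default_factory=list)


def roi_footprint(area: float, spacing: Sequence[float]) -> tuple[int, int]:
    """Voxel side lengths realising a square of ``area`` mm² on the lattice.

    The square's physical side is sqrt(area); each side is rounded to the
    nearest whole voxel count along its axis, floored at one voxel.  The
    realised area is logged since anisotropic spacing rarely hits the
    nominal area exactly.
    """
    if area <= 0:
        raise ValueError(f"ROI area must be positive, got {area}")
    d0, d1 = float(spacing[0]), float(spacing[1])
    if d0 <= 0 or d1 <= 0:
        raise ValueError(f"in-plane spacing must be positive, got {(d0, d1)}")
    side = float(np.sqrt(area))
    h = max(1, round(side / d0))
    w = max(1, round(side / d1))
    log.debug("roi_footprint: %g mm^2 -> %dx%d voxels (realised %g mm^2)",
              area, h, w, h * d0 * w * d1)
    return h, w


def _block_sums(plane: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sums of every h x w block of a 2D array (integral-image trick)."""
    c = np.cumsum(np.cumsum(plane, axis=0, dtype=float), axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    return c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]


def _valid_blocks(mask_plane: np.ndarray, finite_plane: np.ndarray,
                  h: int, w: int) -> np.ndarray:
    """Boolean map of placements lying wholly in-mask with finite voxels."""
    ok = mask_plane & finite_plane
    if ok.shape[0] < h or ok.shape[1] < w:
        return np.zeros((0, 0), dtype=bool)
    # integer block count equals h*w exactly when every voxel qualifies
    return np.rint(_block_sums(ok.astype(float), h, w)).astype(int) == h * w


def enumerate_placements(
    mask: VolumeGrid, footprint: tuple[int, int]
) -> Iterator[SquareROI]:
    """Every axial placement of the footprint lying wholly inside the mask.

    Yields in deterministic scan order: slice, then row, then column.  An
    empty result is legal (mask smaller than the footprint).
    """
    h, w = footprint
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("tumour mask is empty")
    area = h * mask.spacing[0] * w * mask.spacing[1]
    for k in range(m.shape[2]):
        valid = _valid_blocks(m[:, :, k], np.ones_like(m[:, :, k]), h, w)
        for i, j in np.argwhere(valid):
            yield SquareROI(slice=k, row0=int(i), col0=int(j),
                            h_vox=h, w_vox=w, nominal_area=area)


def find_extreme_roi(
    vol: VolumeGrid,
    mask: VolumeGrid,
    area: float,
    mode: str,
) -> tuple[SquareROI, float]:
    """The square placement optimising the within-ROI mean.

    ``mode`` is ``'min_mean'`` (lowest mean, for ADC) or ``'max_mean'``
    (highest mean, for CBF).  Ties break by scan order — the first placement
    encountered wins.  Placements containing non-finite voxels are skipped.
    """
    if mode not in ("min_mean", "max_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    _require_aligned(vol, mask)
    h, w = roi_footprint(area, mask.spacing[:2])
    m = np.asarray(mask.values, dtype=bool)
    v = np.asarray(vol.values, dtype=float)
    best: tuple[SquareROI, float] | None = None
    sign = 1.0 if mode == "min_mean" else -1.0
    for k in range(m.shape[2]):
        plane_mask = m[:, :, k]
        if not plane_mask.any():
            continue
        finite = np.isfinite(v[:, :, k])
        valid = _valid_blocks(plane_mask, finite, h, w)
        if valid.size == 0 or not valid.any():
            continue
        sums = _block_sums(np.where(finite, v[:, :, k], 0.0), h, w)
        means = sums / (h * w)
        score = np.where(valid, sign * means, np.inf)
        idx = np.unravel_index(np.argmin(score), score.shape)  # first in scan order
        if not np.isfinite(score[idx]):
            continue
        cand_mean = float(means[idx])
        if best is None or sign * cand_mean < sign * best[1]:
            roi = SquareROI(slice=k, row0=int(idx[0]), col0=int(idx[1]),
                            h_vox=h, w_vox=w, nominal_area=area)
            best = (roi, cand_mean)
    if best is None:
        raise NoPlacementError(
            f"no {h}x{w}-voxel placement (nominal {area} mm^2) fits inside a "
            f"mask of {int(m.sum())} voxel(s)"
        )
    return best


def gm_reference_cbf(
    cbf: VolumeGrid,
    gm_mask: VolumeGrid,
    tumour_mask: VolumeGrid,
) -> float:
    """Mean grey-matter CBF on the axial slice at the tumour's mid-point.

    The mid-slice is floor((first + last tumour slice)/2); grey-matter
    voxels overlapping the tumour mask are excluded, as are non-finite
    voxels.  Raises :class:`EmptyReferenceError` when nothing is eligible
    (a caller may then fall back to a manual contralateral grey-matter ROI).
    """
    _require_aligned(cbf, gm_mask, tumour_mask)
    tm = np.asarray(tumour_mask.values, dtype=bool)
    gm = np.asarray(gm_mask.values, dtype=bool)
    if not tm.any():
        raise ValueError("tumour mask is empty")
    if not gm.any():
        raise ValueError("grey-matter mask is empty")
    slices = np.flatnonzero(tm.any(axis=(0, 1)))
    mid = int((slices[0] + slices[-1]) // 2)
    eligible = gm[:, :, mid] & ~tm[:, :, mid] & np.isfinite(cbf.values[:, :, mid])
    if not eligible.any():
        raise EmptyReferenceError(
            f"no grey-matter voxels outside the tumour on mid-slice {mid}"
        )
    return float(np.mean(cbf.values[:, :, mid][eligible]))


def whole_tumour_stats(vol: VolumeGrid, mask: VolumeGrid) -> tuple[float, float, float]:
    """(mean, min, max) over all finite in-mask voxels."""
    _require_aligned(vol, mask)
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ValueError("tumour mask is empty")
    vals = np.asarray(vol.values, dtype=float)[m]
    finite = np.isfinite(vals)
    n_bad = int(vals.size - np.count_nonzero(finite))
    if n_bad:
        log.info("whole_tumour_stats: %d non-finite in-mask voxel(s) excluded", n_bad)
    vals = vals[finite]
    if vals.size == 0:
        raise ValueError("all in-mask voxels are non-finite")
    return float(vals.mean()), float(vals.min()), float(vals.max())


def extract_measurements(
    adc: VolumeGrid,
    cbf: VolumeGrid | None,
    mask: VolumeGrid,
    gm_mask: VolumeGrid | None,
    area: float = 50.0,
) -> TumourMeasurements:
    """Full biomarker extraction for one tumour.

    The ADC ROI is placed at the lowest-mean location and yields both the
    ROI mean and the minimum voxel; the CBF ROI is placed independently at
    the highest-mean location and yields the maximum voxel.  nCBF_ROI-max
    divides that maximum by the mid-slice grey-matter reference; a failed
    reference leaves it unset with a flag.
    """
    out = TumourMeasurements(roi_area=area)
    adc_roi, _ = find_extreme_roi(adc, mask, area, "min_mean")
    out.adc_roi = adc_roi
    block = adc.values[adc_roi.voxel_block()]
    # recompute from the block: exact, and consistent with the ROI minimum
    out.adc_roi_mean = float(np.nanmean(block))
    out.adc_roi_min = float(np.nanmin(block))
    wt_mean, wt_min, wt_max = whole_tumour_stats(adc, mask)
    out.whole_tumour["adc"] = {"mean": wt_mean, "min": wt_min, "max": wt_max}
    if cbf is not None:
        cbf_roi, _ = find_extreme_roi(cbf, mask, area, "max_mean")
        out.cbf_roi = cbf_roi
        out.cbf_roi_max = float(np.nanmax(cbf.values[cbf_roi.voxel_block()]))
        wt = whole_tumour_stats(cbf, mask)
        out.whole_tumour["cbf"] = {"mean": wt[0], "min": wt[1], "max": wt[2]}
        if gm_mask is not None:
            try:
                out.cbf_gm = gm_reference_cbf(cbf, gm_mask, mask)
                out.ncbf_roi_max = out.cbf_roi_max / out.cbf_gm
            except EmptyReferenceError as exc:
                out.flags.append(f"gm_reference_failed: {exc}")
        else:
            out.flags.append("no_gm_mask")
    return out


def roi_size_sweep(
    adc: VolumeGrid,
    cbf: VolumeGrid | None,
    mask: VolumeGrid,
    gm_mask: VolumeGrid | None,
    areas: Sequence[float] = DEFAULT_AREAS,
) -> dict[float, TumourMeasurements | None]:
    """Repeat the extraction over several nominal ROI areas.

    Areas whose footprint fits nowhere in the mask map to ``None``.
    """
    out: dict[float, TumourMeasurements | None] = {}
    for area in areas:
        try:
            out[float(area)] = extract_measurements(adc, cbf, mask, gm_mask, area)
        except NoPlacementError:
            log.info("roi_size_sweep: no placement at %g mm^2", area)
            out[float(area)] = None
    return out


def measurements_to_row(case_id: str, m: TumourMeasurements) -> dict:
    """Flatten one tumour's measurements for CSV export."""
    row = {
        "case_id": case_id,
        "area_mm2": m.roi_area,
        "adc_roi_mean": m.adc_roi_mean,
        "adc_roi_min": m.adc_roi_min,
        "cbf_roi_max": m.cbf_roi_max,
        "cbf_gm": m.cbf_gm,
        "ncbf_roi_max": m.ncbf_roi_max,
    }
    for tag, roi in (("adc", m.adc_roi), ("cbf", m.cbf_roi)):
        if roi is not None:
            row[f"{tag}_roi_slice"] = roi.slice
            row[f"{tag}_roi_row0"] = roi.row0
            row[f"{tag}_roi_col0"] = roi.col0
    for map_name, st in m.whole_tumour.items():
        for stat, val in st.items():
            row[f"wt_{map_name}_{stat}"] = val
    row["flags"] = ";".join(m.flags)
    return row


def measurements_to_frame(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows))
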