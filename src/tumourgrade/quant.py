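"""Voxelwise quantification of CBF and ADC parameter maps.

CBF is computed from a single post-labelling-delay pseudo-continuous ASL
acquisition using the standard single-compartment model

    CBF = 6000 * lambda * dM * exp(PLD / T1bl)
          -----------------------------------------    [ml/100g/min]
          2 * alpha * T1bl * M0 * (1 - exp(-tau/T1bl))

where dM is the (already averaged) control-label difference signal, M0 the
equilibrium calibration signal, lambda the blood-brain partition coefficient
(ml/g), alpha the labelling efficiency, T1bl the longitudinal relaxation
time of arterial blood (s), tau the labelling duration (s) and PLD the
post-labelling delay (s).

ADC maps are handled either as scanner-produced volumes needing only a
units conversion into mm²/s, or fitted from a two-point diffusion
acquisition as ADC = ln(S0/Sb)/b.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

log = logging.getLogger(__name__)

#: Unit tags carried by volumes.
UNITS = ("mm2/s", "ml/100g/min", "a.u.", "dimensionless", "mask")


class ShapeMismatchError(ValueError):
    """Two volumes expected to be co-registered differ in shape/spacing."""


class AmbiguousScaleError(ValueError):
    """No single power-of-ten factor brings an ADC map into mm²/s."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D scalar map with voxel spacing; axial slices along the third axis.

    ``values`` is a float (or bool for masks) array indexed
    ``[axis0, axis1, slice]``; ``spacing`` gives the voxel size along each
    axis in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    units: str = "a.u."

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def aligned_with(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def n_nonfinite(self) -> int:
        return int(np.size(self.values) - np.count_nonzero(np.isfinite(self.values)))


def _require_aligned(*grids: VolumeGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise ShapeMismatchError(
                f"volumes are not co-registered: {first.shape}/{first.spacing}"
                f" vs {g.shape}/{g.spacing}"
            )


@dataclass(frozen=True)
class AslParams:
    """Constants of the single-compartment ASL quantification model."""

    lambda_bp: float = 0.9   # blood-brain partition coefficient, ml/g
    alpha: float = 0.85      # labelling efficiency
    t1_blood: float = 1.65   # arterial blood T1, s
    tau_label: float = 1.8   # labelling duration, s
    pld: float = 1.5         # post-labelling delay, s

    def __post_init__(self) -> None:
        for name in ("lambda_bp", "alpha", "t1_blood", "tau_label", "pld"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha > 1:
            raise ValueError("labelling efficiency alpha cannot exceed 1")

    def scale_factor(self) -> float:
        """Multiplier c such that CBF = c * dM / M0."""
        return (6000.0 * self.lambda_bp * math.exp(self.pld / self.t1_blood)) / (
            2.0 * self.alpha * self.t1_blood
            * (1.0 - math.exp(-self.tau_label / self.t1_blood))
        )


def quantify_cbf(
    delta_m: VolumeGrid,
    m0: VolumeGrid,
    params: AslParams | None = None,
    eps_frac: float = 1e-6,
) -> VolumeGrid:
    """Apply the single-compartment model voxelwise.

    Voxels whose M0 falls at or below ``eps_frac`` times M0's robust
    (99th-percentile) maximum are marked NaN rather than divided through;
    their count is logged.  Negative dM (hence negative CBF) is retained.
    """
    params = params or AslParams()
    _require_aligned(delta_m, m0)
    m0v = np.asarray(m0.values, dtype=float)
    robust_max = float(np.nanpercentile(m0v, 99.0))
    eps = eps_frac * robust_max if robust_max > 0 else eps_frac
    valid = np.isfinite(m0v) & np.isfinite(delta_m.values) & (m0v > eps)
    cbf = np.full(delta_m.shape, np.nan)
    cbf[valid] = params.scale_factor() * delta_m.values[valid] / m0v[valid]
    n_bad = int(np.size(cbf) - np.count_nonzero(valid))
    if n_bad:
        log.info("quantify_cbf: %d voxel(s) below the M0 floor marked non-finite",
                 n_bad)
    return VolumeGrid(values=cbf, spacing=delta_m.spacing, units="ml/100g/min")


def delta_m_for_cbf(
    cbf: np.ndarray | float,
    m0: np.ndarray | float,
    params: AslParams | None = None,
) -> np.ndarray:
    """Algebraic inverse of :func:`quantify_cbf`: the dM giving a target CBF."""
    params = params or AslParams()
    return np.asarray(cbf, dtype=float) * np.asarray(m0, dtype=float) / params.scale_factor()


def adc_from_two_b(s0: VolumeGrid, sb: VolumeGrid, b: float = 1000.0) -> VolumeGrid:
    """Two-point mono-exponential ADC fit: ADC = ln(S0/Sb)/b, mm²/s.

    Voxels with non-positive signal are marked NaN.  Voxels where Sb > S0
    yield negative ADC; they are kept and tallied in a warning.
    """
    if b <= 0:
        raise ValueError(f"b value must be positive, got {b}")
    _require_aligned(s0, sb)
    s0v = np.asarray(s0.values, dtype=float)
    sbv = np.asarray(sb.values, dtype=float)
    valid = np.isfinite(s0v) & np.isfinite(sbv) & (s0v > 0) & (sbv > 0)
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0v[valid] / sbv[valid]) / b
    n_neg = int(np.count_nonzero(adc[valid] < 0))
    if n_neg:
        log.warning("adc_from_two_b: %d voxel(s) with Sb > S0 gave negative ADC",
                    n_neg)
    return VolumeGrid(values=adc, spacing=s0.spacing, units="mm2/s")


#: Typical magnitude of brain-tissue ADC in mm²/s; 'auto' scaling targets it.
_ADC_TARGET = 1e-3
_ADC_BAND = (1e-4, 1e-2)


def convert_adc_units(
    grid: VolumeGrid,
    scale_hint: str = "auto",
    mask: np.ndarray | None = None,
) -> VolumeGrid:
    """Bring a scanner-exported ADC map into mm²/s.

    ``scale_hint``:
      * ``'auto'``    — choose the power-of-ten factor that moves the median
        (in-mask) value closest to the typical tissue ADC of 1e-3 mm²/s,
        requiring the result to land in [1e-4, 1e-2]; the factor is logged.
      * ``'e-3'``     — values are in 10⁻³ mm²/s units; multiply by 1e-3.
      * ``'e-6_mm2_s'`` — values are in 10⁻⁶ mm²/s units; multiply by 1e-6.
      * ``'none'``    — already mm²/s; returned unchanged.
    """
    if scale_hint == "none":
        return replace(grid, units="mm2/s")
    if scale_hint == "e-3":
        factor = 1e-3
    elif scale_hint == "e-6_mm2_s":
        factor = 1e-6
    elif scale_hint == "auto":
        vals = np.asarray(grid.values, dtype=float)
        if mask is not None:
            vals = vals[np.asarray(mask, dtype=bool)]
        vals = vals[np.isfinite(vals) & (vals > 0)]
        if vals.size == 0:
            raise AmbiguousScaleError("no positive finite voxels to infer scale")
        med = float(np.median(vals))
        candidates = [
            k for k in range(-9, 10)
            if _ADC_BAND[0] <= med * 10.0**k <= _ADC_BAND[1]
        ]
        if not candidates:
            raise AmbiguousScaleError(
                f"no power-of-ten factor brings median {med:g} into mm^2/s"
            )
        dist = [abs(math.log10(med * 10.0**k / _ADC_TARGET)) for k in candidates]
        order = np.argsort(dist)
        if len(candidates) > 1 and abs(dist[order[0]] - dist[order[1]]) < 0.01:
            raise AmbiguousScaleError(
                f"median {med:g} is equidistant between power-of-ten scales"
            )
        factor = 10.0 ** candidates[order[0]]
        log.info("convert_adc_units: auto-selected factor %g (median %g)",
                 factor, med)
    else:
        raise ValueError(f"unknown scale_hint {scale_hint!r}")
    return VolumeGrid(values=grid.values * factor, spacing=grid.spacing,
                      units="mm2/s")


# ---------------------------------------------------------------------------
# NIfTI I/O (unit tags travel in a sidecar JSON next to the image)

def load_nifti(path: str | Path, units: str | None = None) -> VolumeGrid:
    """Read a NIfTI-1 volume; voxel spacing from the header zooms.

    A ``<stem>.json`` sidecar with a ``"units"`` key, when present,
    supplies the unit tag unless ``units`` overrides it.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if units is None:
        sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
        if sidecar.exists():
            units = json.loads(sidecar.read_text()).get("units", "a.u.")
        else:
            units = "a.u."
    return VolumeGrid(values=data, spacing=tuple(float(z) for z in zooms),
                      units=units)


def save_nifti(grid: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI-1 with a units sidecar JSON."""
    path = Path(path)
    affine = np.diag([*grid.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    sidecar = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    sidecar.write_text(json.dumps({"units": grid.units}))


def load_mask(path: str | Path) -> VolumeGrid:
    """Read a 0/1 integer NIfTI mask as a boolean volume."""
    grid = load_nifti(path, units="mask")
    return replace(grid, values=np.asarray(grid.values) > 0.5)
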