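"""Seeded synthetic inputs with known ground truth.

Patient images and reader measurements behind the clinical analyses are not
public, so every pipeline input can be generated here with known truth:

* **study tables** — study-level means drawn from a random-effects model
  (true group mean + between-study Normal(0, tau²) + within-study sampling
  noise), for CI-coverage and recovery tests of the pooling estimator;
* **tumour phantoms** — an ellipsoidal tumour in a 3D grid with a cold
  low-ADC focus and a hot high-CBF focus, a grey-matter shell around it,
  and ASL raw volumes (dM, M0) algebraically consistent with the noiseless
  CBF map;
* **reader pairs** — paired measurements with known multiplicative bias and
  additive noise, for ICC/RPC recovery;
* **labelled cohorts** — per-tumour biomarkers drawn from stated per-grade
  distributions (optionally from a known logistic model), for ROC and
  coefficient-recovery tests.

All generators are pure functions of their spec plus a seed
(``numpy.random.default_rng``); identical reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import _sigmoid
from .meta import StudyRecord
from .agreement import PairedMeasurements
from .quant import AslParams, VolumeGrid, delta_m_for_cbf


# ---------------------------------------------------------------------------
# Study tables

def gen_study_table(
    true_group_means: Mapping[str, float],
    tau: float,
    k_per_group: int,
    n_range: tuple[int, int] = (5, 50),
    sd_frac_range: tuple[float, float] = (0.15, 0.35),
    parameter: str = "ADC_ROI_mean",
    seed: int = 0,
    grade_by_group: Mapping[str, str] | None = None,
) -> list[StudyRecord]:
    """Draw study-level summaries from a random-effects model.

    Each of ``k_per_group`` studies per group reports a mean
    ``mu_g + Normal(0, tau²) + Normal(0, sd²/n)`` with ``n`` uniform in
    ``n_range`` and the reported SD a uniform fraction of ``|mu_g|`` in
    ``sd_frac_range``.  ``grade_by_group`` assigns a WHO grade per group
    (default ``'unknown'``).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if k_per_group < 1:
        raise ValueError("k_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[StudyRecord] = []
    for group in sorted(true_group_means):
        mu = float(true_group_means[group])
        grade = (grade_by_group or {}).get(group, "unknown")
        for i in range(k_per_group):
            n = int(rng.integers(n_range[0], n_range[1] + 1))
            sd = float(rng.uniform(*sd_frac_range) * abs(mu))
            mean = mu + rng.normal(0.0, tau) + rng.normal(0.0, sd / np.sqrt(n))
            records.append(StudyRecord(
                study_id=f"{group}_study{i}", parameter=parameter,
                subtype=group, who_grade=grade, n=n,
                mean=float(mean), sd=sd,
            ))
    return records


# ---------------------------------------------------------------------------
# Tumour phantoms

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic tumour case.

    Defaults give a 64x64x16 grid of 2x2x4 mm voxels — small enough that
    the full pipeline runs in seconds — with an ellipsoidal tumour, a cold
    ADC focus and hot CBF focus inside it, and a grey-matter shell around
    it.  Intensities sit at clinically plausible levels (ADC in mm²/s, CBF
    in ml/100g/min).
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    tumour_centre: tuple[float, float, float] = (32.0, 32.0, 8.0)   # voxels
    tumour_semiaxes: tuple[float, float, float] = (12.0, 12.0, 4.0)  # voxels
    gm_shell_scale: tuple[float, float] = (1.6, 2.0)
    background_adc: float = 0.8e-3
    tumour_adc: float = 1.1e-3
    adc_focus_centre: tuple[float, float, float] = (28.0, 28.0, 8.0)
    adc_focus_radius: float = 4.0       # voxels
    adc_focus_value: float = 0.6e-3
    background_cbf: float = 20.0
    tumour_cbf: float = 40.0
    cbf_focus_centre: tuple[float, float, float] = (37.0, 36.0, 8.0)
    cbf_focus_radius: float = 4.0
    cbf_focus_value: float = 120.0
    gm_cbf: float = 60.0
    gm_adc: float = 0.85e-3
    m0_value: float = 1000.0
    noise_sd_adc: float = 0.0
    noise_sd_cbf: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_adc < 0 or self.noise_sd_cbf < 0:
            raise ValueError("noise SDs must be >= 0")
        for name in ("adc_focus_centre", "cbf_focus_centre"):
            c = np.asarray(getattr(self, name))
            r = np.asarray(self.tumour_centre)
            ax = np.asarray(self.tumour_semiaxes)
            if np.sum(((c - r) / ax) ** 2) > 1.0:
                raise ValueError(f"{name} lies outside the tumour ellipsoid")


def _ellipsoid(shape, centre, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centre, semiaxes))
    return d2 <= 1.0


def _ball(shape, centre, radius) -> np.ndarray:
    return _ellipsoid(shape, centre, (radius, radius, radius))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    adc_focus_centre: tuple[float, float, float]
    adc_focus_value: float
    cbf_focus_centre: tuple[float, float, float]
    cbf_focus_value: float
    gm_cbf: float
    ncbf_roi_max: float


def gen_phantom(
    spec: PhantomSpec, asl_params: AslParams | None = None
) -> dict:
    """Build one phantom case: maps, raw ASL volumes, masks and truth.

    Returns a dict with keys ``adc``, ``cbf``, ``delta_m``, ``m0``
    (:class:`VolumeGrid`), ``tumour_mask``, ``gm_mask`` (boolean grids),
    ``cbf_noiseless`` and ``truth``.  The dM volume is the algebraic
    inverse of the CBF quantification model applied to the *noiseless* CBF
    map, so re-quantifying it reproduces that map to machine precision.
    """
    asl_params = asl_params or AslParams()
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape

    tumour = _ellipsoid(shape, spec.tumour_centre, spec.tumour_semiaxes)
    if not tumour.any():
        raise ValueError("tumour ellipsoid does not intersect the grid")
    inner = _ellipsoid(shape, spec.tumour_centre,
                       tuple(a * spec.gm_shell_scale[0] for a in spec.tumour_semiaxes))
    outer = _ellipsoid(shape, spec.tumour_centre,
                       tuple(a * spec.gm_shell_scale[1] for a in spec.tumour_semiaxes))
    gm = outer & ~inner & ~tumour

    adc = np.full(shape, spec.background_adc)
    adc[gm] = spec.gm_adc
    adc[tumour] = spec.tumour_adc
    cold = _ball(shape, spec.adc_focus_centre, spec.adc_focus_radius) & tumour
    adc[cold] = spec.adc_focus_value

    cbf = np.full(shape, spec.background_cbf)
    cbf[gm] = spec.gm_cbf
    cbf[tumour] = spec.tumour_cbf
    hot = _ball(shape, spec.cbf_focus_centre, spec.cbf_focus_radius) & tumour
    cbf[hot] = spec.cbf_focus_value

    m0 = np.full(shape, spec.m0_value)
    delta_m = delta_m_for_cbf(cbf, m0, asl_params)

    adc_noisy = adc + rng.normal(0.0, spec.noise_sd_adc, shape) \
        if spec.noise_sd_adc > 0 else adc.copy()
    cbf_noisy = cbf + rng.normal(0.0, spec.noise_sd_cbf, shape) \
        if spec.noise_sd_cbf > 0 else cbf.copy()

    sp = spec.spacing
    truth = PhantomTruth(
        adc_focus_centre=spec.adc_focus_centre,
        adc_focus_value=spec.adc_focus_value,
        cbf_focus_centre=spec.cbf_focus_centre,
        cbf_focus_value=spec.cbf_focus_value,
        gm_cbf=spec.gm_cbf,
        ncbf_roi_max=spec.cbf_focus_value / spec.gm_cbf,
    )
    return {
        "adc": VolumeGrid(adc_noisy, sp, "mm2/s"),
        "cbf": VolumeGrid(cbf_noisy, sp, "ml/100g/min"),
        "cbf_noiseless": VolumeGrid(cbf, sp, "ml/100g/min"),
        "delta_m": VolumeGrid(delta_m, sp, "a.u."),
        "m0": VolumeGrid(m0, sp, "a.u."),
        "tumour_mask": VolumeGrid(tumour, sp, "mask"),
        "gm_mask": VolumeGrid(gm, sp, "mask"),
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Reader pairs

def gen_reader_pairs(
    true_values: Sequence[float],
    bias_fraction: float,
    noise_sd: float,
    seed: int = 0,
    parameter: str = "ADC_ROI_mean",
    roles: tuple[str, str] = ("reader", "gold"),
) -> PairedMeasurements:
    """Paired measurements a = truth*(1+bias)+e1, b = truth+e2.

    Both noise terms are independent Normal(0, noise_sd²); role ``b`` plays
    the gold standard by default.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.asarray(true_values, dtype=float)
    a = t * (1.0 + bias_fraction) + rng.normal(0.0, noise_sd, t.shape)
    b = t + rng.normal(0.0, noise_sd, t.shape)
    return PairedMeasurements(parameter=parameter,
                              pairs=tuple(zip(a.tolist(), b.tolist())),
                              roles=roles)


# ---------------------------------------------------------------------------
# Labelled cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Generating distributions for a two-class biomarker cohort.

    Defaults mirror a small validation cohort after excluding diffuse
    midline glioma: 13 low-grade and 12 high-grade tumours, low-grade
    tumours with high ADC / low nCBF and vice versa, and a mild negative
    ADC–nCBF correlation within class.  Scales: ADC in mm²/s, nCBF
    dimensionless.
    """

    n_low: int = 13
    n_high: int = 12
    adc_mean: Mapping[str, float] = field(
        default_factory=lambda: {"low": 1.30e-3, "high": 0.72e-3})
    adc_sd: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.25e-3, "high": 0.14e-3})
    ncbf_mean: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.95, "high": 1.95})
    ncbf_sd: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.35, "high": 0.60})
    adc_ncbf_corr: Mapping[str, float] = field(
        default_factory=lambda: {"low": -0.2, "high": -0.2})
    adc_min_offset_mean: float = 0.15e-3
    adc_min_offset_sd: float = 0.05e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for m in (self.adc_sd, self.ncbf_sd):
            if any(v < 0 for v in m.values()):
                raise ValueError("SDs must be >= 0")
        if any(abs(r) > 1 for r in self.adc_ncbf_corr.values()):
            raise ValueError("correlations must lie in [-1, 1]")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a labelled cohort of per-tumour biomarkers.

    Columns: ``case_id, subtype, grade, adc_roi_mean, adc_roi_min,
    ncbf_roi_max``.  Within each class (adc, ncbf) is bivariate normal with
    the stated correlation; adc_roi_min is adc_roi_mean minus a
    non-negative offset.  Subtype labels are generic placeholders.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for grade, n in (("low", spec.n_low), ("high", spec.n_high)):
        mu = np.array([spec.adc_mean[grade], spec.ncbf_mean[grade]])
        sd = np.array([spec.adc_sd[grade], spec.ncbf_sd[grade]])
        r = spec.adc_ncbf_corr[grade]
        cov = np.array([[sd[0] ** 2, r * sd[0] * sd[1]],
                        [r * sd[0] * sd[1], sd[1] ** 2]])
        draws = rng.multivariate_normal(mu, cov, size=n)
        offsets = np.abs(rng.normal(spec.adc_min_offset_mean,
                                    spec.adc_min_offset_sd, n))
        for i in range(n):
            adc_mean = float(draws[i, 0])
            rows.append({
                "case_id": f"{grade}_{i:03d}",
                "subtype": f"synthetic_{grade}_grade",
                "grade": grade,
                "adc_roi_mean": adc_mean,
                "adc_roi_min": adc_mean - float(offsets[i]),
                "ncbf_roi_max": float(draws[i, 1]),
            })
    return pd.DataFrame(rows)


def gen_cohort_from_logistic(
    beta0: float,
    beta_adc: float,
    beta_ncbf: float,
    n: int,
    seed: int = 0,
    adc_range: tuple[float, float] = (0.4e-3, 1.8e-3),
    ncbf_range: tuple[float, float] = (0.3, 3.5),
) -> pd.DataFrame:
    """Cohort whose labels are Bernoulli draws from a known logistic model.

    Predictors are uniform over their stated ranges; the high-grade
    probability is sigmoid(beta0 + beta_adc*adc + beta_ncbf*ncbf) with
    coefficients on the input (mm²/s) scale.  Used for coefficient-recovery
    tests.
    """
    rng = np.random.default_rng(seed)
    adc = rng.uniform(*adc_range, n)
    ncbf = rng.uniform(*ncbf_range, n)
    p = _sigmoid(beta0 + beta_adc * adc + beta_ncbf * ncbf)
    y = rng.random(n) < p
    return pd.DataFrame({
        "case_id": [f"sim_{i:05d}" for i in range(n)],
        "subtype": "synthetic",
        "grade": np.where(y, "high", "low"),
        "adc_roi_mean": adc,
        "adc_roi_min": adc,
        "ncbf_roi_max": ncbf,
    })
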