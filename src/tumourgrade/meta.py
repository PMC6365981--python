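"""Random-effects pooling of study-level tumour biomarker summaries.

Published studies report, per histological subtype, the mean and SD of a
biomarker (ADC_ROI-mean, ADC_ROI-min in mm²/s; nCBF_ROI-max dimensionless)
over ``n`` patients.  This module combines such study-level summaries with
the DerSimonian–Laird (DL) random-effects estimator, compares groups with a
weighted one-way ANOVA of the pooled summary measures (Tukey-HSD adjusted
pairwise contrasts), and derives "target regions" — the gap between the 95%
confidence intervals of the low-grade and high-grade pooled estimates, inside
which a clinical classification threshold should fall.

The DL model treats study ``i``'s reported mean ``m_i`` as

    m_i ~ Normal(mu, tau^2 + v_i),    v_i = sd_i^2 / n_i,

with ``tau^2`` the between-study variance estimated by the method of
moments from Cochran's Q, and pools with weights ``1 / (v_i + tau^2)``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: Recognised biomarker labels.
PARAMETERS = ("ADC_ROI_mean", "ADC_ROI_min", "nCBF_ROI_max")

#: Parameter families used for patient counting (a study reporting both ADC
#: parameters contributes its patients once to the ADC family).
PARAMETER_FAMILY = {
    "ADC_ROI_mean": "ADC",
    "ADC_ROI_min": "ADC",
    "nCBF_ROI_max": "CBF",
}

WHO_GRADES = ("I", "II", "III", "IV", "unknown")
WHO_TO_BINARY = {"I": "low", "II": "low", "III": "high", "IV": "high"}

#: Path of the bundled study table (study ids and patient counts transcribed
#: from the published study list; subtype splits and means/SDs synthetic).
TABLE1_PATH = Path(__file__).parent / "data" / "table1.csv"


class SchemaError(ValueError):
    """The study table is missing a required column."""


class RowParseError(ValueError):
    """A study-table row carries a non-numeric or invalid value."""


class DegenerateVarianceError(ValueError):
    """A pooled computation encountered a zero variance it cannot weight."""


@dataclass(frozen=True)
class StudyRecord:
    """One study x parameter x subtype summary line."""

    study_id: str
    parameter: str
    subtype: str
    who_grade: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise RowParseError(f"unknown parameter label {self.parameter!r}")
        if self.who_grade not in WHO_GRADES:
            raise RowParseError(f"unknown WHO grade {self.who_grade!r}")
        if self.n < 1:
            raise RowParseError(f"n must be >= 1, got {self.n}")
        if self.sd < 0:
            raise RowParseError(f"sd must be >= 0, got {self.sd}")

    @property
    def variance(self) -> float:
        """Within-study variance of the reported mean: sd^2 / n."""
        return self.sd**2 / self.n


@dataclass(frozen=True)
class SummaryEstimate:
    """Pooled random-effects estimate for one group of studies."""

    group: str
    parameter: str
    k: int
    N: int
    pooled_mean: float
    tau2: float
    se_pooled: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class TargetRegion:
    """Interval between the non-overlapping 95% CIs of two grade groups."""

    parameter: str
    lower: float | None
    upper: float | None
    empty: bool


def load_study_table(path: str | Path | None = None) -> list[StudyRecord]:
    """Read a study-summary CSV into :class:`StudyRecord` objects.

    ``path=None`` loads the bundled transcription of the meta-analysis study
    list (whose subtype-level means/SDs are synthetic stand-ins; see the
    fixture header).  ADC rows are validated to be in mm²/s: a mean above
    0.1 indicates values left on a 10⁻³ scale and is rejected.
    """
    path = TABLE1_PATH if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    required = ["study_id", "parameter", "subtype", "who_grade", "n", "mean", "sd"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"study table is missing required column {col!r}")
    records: list[StudyRecord] = []
    for idx, row in df.iterrows():
        try:
            n = int(row["n"])
            mean = float(row["mean"])
            sd = float(row["sd"])
        except (TypeError, ValueError) as exc:
            raise RowParseError(f"row {idx}: non-numeric n/mean/sd") from exc
        rec = StudyRecord(
            study_id=str(row["study_id"]),
            parameter=str(row["parameter"]),
            subtype=str(row["subtype"]),
            who_grade=str(row["who_grade"]),
            n=n,
            mean=mean,
            sd=sd,
        )
        if PARAMETER_FAMILY[rec.parameter] == "ADC" and rec.mean > 0.1:
            raise RowParseError(
                f"row {idx}: ADC mean {rec.mean} not in mm^2/s "
                "(values look like 10^-3 units)"
            )
        records.append(rec)
    log.info("loaded %d study records from %s", len(records), path)
    return records


def count_studies(records: Iterable[StudyRecord]) -> int:
    """Number of distinct studies contributing any parameter."""
    return len({r.study_id for r in records})


def count_patients(records: Iterable[StudyRecord], family: str) -> int:
    """Total patients contributing to a parameter family ('ADC' or 'CBF').

    Patients are counted once per (study, subtype) even when a study reports
    both ADC_ROI_mean and ADC_ROI_min for the same patients.
    """
    seen: dict[tuple[str, str], int] = {}
    for r in records:
        if PARAMETER_FAMILY[r.parameter] != family:
            continue
        key = (r.study_id, r.subtype)
        if key in seen and seen[key] != r.n:
            raise RowParseError(
                f"inconsistent n for study {r.study_id!r} subtype {r.subtype!r}"
            )
        seen[key] = r.n
    return sum(seen.values())


def dl_pool(
    records: Sequence[StudyRecord],
    group: str = "",
    tau2: float | None = None,
) -> SummaryEstimate:
    """DerSimonian–Laird random-effects pooling of one group of studies.

    With fixed-effect weights ``w_i = 1/v_i`` and fixed-effect mean
    ``m_FE``, heterogeneity is ``Q = sum w_i (m_i - m_FE)^2`` and

        tau^2 = max(0, (Q - (k-1)) / (sum w_i - sum w_i^2 / sum w_i)).

    Random-effects weights ``w*_i = 1/(v_i + tau^2)`` give the pooled mean,
    its SE ``(sum w*_i)^{-1/2}`` and the normal-approximation 95% CI.  A
    single study is returned as-is with ``tau^2 = 0``.  Passing ``tau2``
    skips the moment estimate and pools with the supplied between-study
    variance (used when tau^2 is shared across groups).
    """
    # canonical ordering makes the pooled floating-point sums independent of
    # the caller's record order
    records = sorted(records, key=lambda r: (r.study_id, r.subtype, r.n,
                                             r.mean, r.sd))
    if not records:
        raise ValueError("cannot pool an empty group of studies")
    params = {r.parameter for r in records}
    if len(params) > 1:
        raise ValueError(f"cannot pool across parameters: {sorted(params)}")
    parameter = records[0].parameter
    k = len(records)
    N = sum(r.n for r in records)
    means = np.array([r.mean for r in records], dtype=float)
    v = np.array([r.variance for r in records], dtype=float)

    if k == 1:
        pooled = float(means[0])
        t2 = 0.0 if tau2 is None else float(tau2)
        se = math.sqrt(v[0] + t2)
    else:
        if np.any(v == 0):
            raise DegenerateVarianceError(
                "a study with zero within-study variance cannot be weighted"
            )
        if tau2 is None:
            t2 = estimate_tau2(means, v)
        else:
            t2 = float(tau2)
        w_star = 1.0 / (v + t2)
        pooled = float(np.sum(w_star * means) / np.sum(w_star))
        se = float(np.sum(w_star) ** -0.5)
    ci = (pooled - 1.96 * se, pooled + 1.96 * se)
    return SummaryEstimate(
        group=group, parameter=parameter, k=k, N=N,
        pooled_mean=pooled, tau2=t2, se_pooled=se, ci95=ci,
    )


def estimate_tau2(means: np.ndarray, variances: np.ndarray) -> float:
    """Method-of-moments between-study variance from Cochran's Q."""
    k = len(means)
    if k < 2:
        return 0.0
    w = 1.0 / variances
    m_fe = np.sum(w * means) / np.sum(w)
    q = float(np.sum(w * (means - m_fe) ** 2))
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    return max(0.0, (q - (k - 1)) / denom)


def _group_key(record: StudyRecord, grouping: str) -> str | None:
    if grouping == "subtype":
        return record.subtype
    if grouping == "who_grade":
        return None if record.who_grade == "unknown" else record.who_grade
    if grouping == "binary_grade":
        return WHO_TO_BINARY.get(record.who_grade)
    raise ValueError(f"unknown grouping {grouping!r}")


def pool_by_group(
    records: Sequence[StudyRecord],
    grouping: str,
    min_patients: int = 2,
    tau2_share: str = "group",
) -> list[SummaryEstimate]:
    """Pool one parameter's records within each group of a grouping.

    ``grouping`` is ``subtype``, ``who_grade`` or ``binary_grade`` (WHO I-II
    -> low, III-IV -> high).  Groups totalling fewer than ``min_patients``
    patients after combination are omitted (and logged).  Records with
    unknown WHO grade are excluded from grade groupings with a warning.

    ``tau2_share='group'`` estimates tau^2 separately within each group;
    ``'modality'`` estimates one tau^2 from all of the parameter's studies
    and applies it to every group.
    """
    records = list(records)
    params = {r.parameter for r in records}
    if len(params) > 1:
        raise ValueError(f"records must share one parameter, got {sorted(params)}")
    if tau2_share not in ("group", "modality"):
        raise ValueError(f"unknown tau2_share mode {tau2_share!r}")

    shared_tau2: float | None = None
    if tau2_share == "modality" and len(records) >= 2:
        means = np.array([r.mean for r in records])
        v = np.array([r.variance for r in records])
        if np.any(v == 0):
            raise DegenerateVarianceError("zero within-study variance")
        shared_tau2 = estimate_tau2(means, v)

    groups: dict[str, list[StudyRecord]] = {}
    for r in records:
        key = _group_key(r, grouping)
        if key is None:
            log.warning("record %s has unknown WHO grade; excluded from %s",
                        r.study_id, grouping)
            continue
        groups.setdefault(key, []).append(r)

    estimates: list[SummaryEstimate] = []
    for key in sorted(groups):
        members = groups[key]
        total_n = sum(r.n for r in members)
        if total_n < min_patients:
            log.info("group %r omitted: %d patient(s) < min_patients=%d",
                     key, total_n, min_patients)
            continue
        estimates.append(dl_pool(members, group=key, tau2=shared_tau2))
    return estimates


def subgroup_anova(
    estimates: Sequence[SummaryEstimate],
) -> tuple[float, int, float]:
    """Weighted one-way ANOVA of subgroup summary estimates.

    Treats each group's pooled mean as an observation with known SE and
    computes the between-group heterogeneity statistic

        Q_between = sum_g w_g (mu_g - mu_hat)^2,   w_g = 1/se_g^2,

    referred to a chi-square distribution with G-1 degrees of freedom.
    Returns ``(Q_between, df, p)``.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("subgroup ANOVA requires at least two groups")
    if len({e.parameter for e in estimates}) > 1:
        raise ValueError("groups must share one parameter")
    se = np.array([e.se_pooled for e in estimates])
    if np.any(se <= 0):
        raise DegenerateVarianceError("a group with zero SE cannot be weighted")
    mu = np.array([e.pooled_mean for e in estimates])
    w = se**-2.0
    mu_hat = np.sum(w * mu) / np.sum(w)
    q = float(np.sum(w * (mu - mu_hat) ** 2))
    df = len(estimates) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def pairwise_tukey(estimates: Sequence[SummaryEstimate]) -> pd.DataFrame:
    """All pairwise group contrasts with Tukey-HSD adjusted p-values.

    Each pair's z statistic is ``(mu_a - mu_b)/sqrt(se_a^2 + se_b^2)``; the
    adjusted p is the upper tail of the studentized range with G groups and
    infinite degrees of freedom evaluated at ``|z|*sqrt(2)`` (the summary
    estimates carry no residual df, so the large-sample range is used).
    """
    estimates = list(estimates)
    g = len(estimates)
    if g < 2:
        raise ValueError("pairwise comparisons require at least two groups")
    if len({e.parameter for e in estimates}) > 1:
        raise ValueError("groups must share one parameter")
    se = np.array([e.se_pooled for e in estimates])
    if np.any(se <= 0):
        raise DegenerateVarianceError("a group with zero SE cannot be compared")
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            a, b = estimates[i], estimates[j]
            z = (a.pooled_mean - b.pooled_mean) / math.hypot(a.se_pooled, b.se_pooled)
            p_adj = float(stats.studentized_range.sf(abs(z) * math.sqrt(2.0),
                                                     k=g, df=np.inf))
            rows.append({"group_a": a.group, "group_b": b.group,
                         "z": z, "adjusted_p": min(1.0, p_adj)})
    return pd.DataFrame(rows)


def derive_target_region(
    low: SummaryEstimate, high: SummaryEstimate
) -> TargetRegion:
    """Gap between the 95% CIs of the low- and high-grade pooled estimates.

    For ADC the low-grade group sits higher, so the region runs from the
    high group's CI top to the low group's CI bottom; for nCBF the reverse.
    Overlapping CIs yield an empty region.
    """
    if low.parameter != high.parameter:
        raise ValueError(
            f"parameter mismatch: {low.parameter!r} vs {high.parameter!r}"
        )
    if low.pooled_mean >= high.pooled_mean:
        lower, upper = high.ci95[1], low.ci95[0]
    else:
        lower, upper = low.ci95[1], high.ci95[0]
    if lower >= upper:
        return TargetRegion(parameter=low.parameter, lower=None, upper=None,
                            empty=True)
    return TargetRegion(parameter=low.parameter, lower=lower, upper=upper,
                        empty=False)


def estimates_to_frame(estimates: Sequence[SummaryEstimate]) -> pd.DataFrame:
    """Flatten summary estimates into a DataFrame for CSV export."""
    return pd.DataFrame(
        {
            "group": e.group,
            "parameter": e.parameter,
            "k": e.k,
            "N": e.N,
            "pooled_mean": e.pooled_mean,
            "tau2": e.tau2,
            "se_pooled": e.se_pooled,
            "ci95_lo": e.ci95[0],
            "ci95_hi": e.ci95[1],
        }
        for e in estimates
    )


def meta_report(records: Sequence[StudyRecord],
                min_patients: int = 2,
                tau2_share: str = "group") -> dict:
    """Full meta-analysis over every parameter and grouping.

    Returns a JSON-serialisable report: per-parameter counts, pooled
    estimates for subtype / WHO-grade / binary groupings, omnibus and
    pairwise tests, and the low/high target region.
    """
    records = list(records)
    report: dict = {
        "n_studies": count_studies(records),
        "n_patients_adc": count_patients(records, "ADC"),
        "n_patients_cbf": count_patients(records, "CBF"),
        "parameters": {},
    }
    for parameter in PARAMETERS:
        sub = [r for r in records if r.parameter == parameter]
        if not sub:
            continue
        entry: dict = {}
        for grouping in ("subtype", "who_grade", "binary_grade"):
            ests = pool_by_group(sub, grouping, min_patients=min_patients,
                                 tau2_share=tau2_share)
            block: dict = {
                "estimates": estimates_to_frame(ests).to_dict(orient="records")
            }
            if len(ests) >= 2:
                q, df, p = subgroup_anova(ests)
                block["anova"] = {"Q": q, "df": df, "p": p}
                block["tukey"] = pairwise_tukey(ests).to_dict(orient="records")
            if grouping == "binary_grade":
                by_group = {e.group: e for e in ests}
                if "low" in by_group and "high" in by_group:
                    region = derive_target_region(by_group["low"], by_group["high"])
                    block["target_region"] = {
                        "lower": region.lower, "upper": region.upper,
                        "empty": region.empty,
                    }
            entry[grouping] = block
        report["parameters"][parameter] = entry
    return report


def write_meta_report(report: dict, out_dir: str | Path) -> None:
    """Write the meta-analysis report as JSON plus per-grouping CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "meta_report.json").write_text(json.dumps(report, indent=2))
    rows = []
    for parameter, entry in report["parameters"].items():
        for grouping, block in entry.items():
            for est in block["estimates"]:
                rows.append({"grouping": grouping, **est})
    pd.DataFrame(rows).to_csv(out / "summary_estimates.csv", index=False)
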