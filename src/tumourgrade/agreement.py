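"""Inter-reader and reader-vs-automated agreement statistics.

Two radiologists (or a radiologist and the automated gold standard) each
measure the same biomarker in every tumour of a cohort.  Agreement is
summarised by:

* **ICC** — intraclass correlation, two-way random effects, absolute
  agreement, single measures (ICC(A,1)): readers are interchangeable draws
  from a population of raters, and systematic offsets between them count
  against agreement.  A consistency-type ICC (ICC(C,1)) is available.
* **RPC** — reproducibility coefficient, 1.96 x the sample SD of the paired
  differences: the half-width of the 95% limits of agreement.
* **bias %** — mean of the per-pair relative differences 100*(a-b)/b
  against the gold-standard series b (only meaningful for reader-vs-
  automated roles); a pooled alternative divides the mean difference by the
  mean gold-standard value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class UndefinedICCError(ValueError):
    """Total variance is zero; the ICC is undefined."""


@dataclass(frozen=True)
class PairedMeasurements:
    """Per-tumour paired values for one biomarker.

    ``roles`` is ``('reader', 'reader')`` for inter-reader data or
    ``('reader', 'gold')`` when the second series is the automated gold
    standard.
    """

    parameter: str
    pairs: tuple[tuple[float, float], ...]
    roles: tuple[str, str] = ("reader", "reader")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be a sequence of (value_a, value_b)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("paired values must be finite")
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class AgreementStats:
    icc: float
    rpc: float
    bias_percent: float | None


def icc_absolute(data: PairedMeasurements, form: str = "absolute") -> float:
    """Single-measure ICC from the two-rater ANOVA mean squares.

    With n subjects and k=2 raters, the two-way decomposition gives the
    between-subject (MSR), between-rater (MSC) and residual (MSE) mean
    squares, and

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)

    ``form`` selects ``'absolute'`` (default) or ``'consistency'``.
    """
    if form not in ("absolute", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    a, b = data.arrays()
    n = a.size
    if n < 2:
        raise ValueError("ICC requires at least two pairs")
    k = 2
    x = np.stack([a, b], axis=1)  # n x k
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = k * float(((subj_means - grand) ** 2).sum())
    ss_cols = n * float(((rater_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise UndefinedICCError("all measurements identical; ICC undefined")
    if form == "consistency":
        denom = msr + (k - 1) * mse
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise UndefinedICCError("zero denominator in ICC")
    return float((msr - mse) / denom)


def rpc_and_bias(
    data: PairedMeasurements,
    bias_mode: str = "per_pair",
) -> tuple[float, float | None]:
    """Reproducibility coefficient and percentage bias of a paired series.

    RPC = 1.96 x SD(a - b) with the sample (n-1) SD.  bias_percent is
    computed only when the second role is the gold standard: ``'per_pair'``
    averages 100*(a-b)/b over pairs; ``'pooled'`` uses
    100*mean(a-b)/mean(b).
    """
    if bias_mode not in ("per_pair", "pooled"):
        raise ValueError(f"unknown bias_mode {bias_mode!r}")
    a, b = data.arrays()
    if a.size < 2:
        raise ValueError("RPC requires at least two pairs")
    rpc = 1.96 * float(np.std(a - b, ddof=1))
    bias: float | None = None
    if data.roles[1] == "gold":
        if bias_mode == "per_pair":
            if np.any(b == 0):
                raise ZeroDivisionError(
                    "gold-standard value of zero in percentage bias"
                )
            bias = float(np.mean(100.0 * (a - b) / b))
        else:
            denom = float(np.mean(b))
            if denom == 0:
                raise ZeroDivisionError("mean gold-standard value is zero")
            bias = float(100.0 * np.mean(a - b) / denom)
    return rpc, bias


def agreement_stats(data: PairedMeasurements, icc_form: str = "absolute",
                    bias_mode: str = "per_pair") -> AgreementStats:
    rpc, bias = rpc_and_bias(data, bias_mode=bias_mode)
    return AgreementStats(icc=icc_absolute(data, form=icc_form), rpc=rpc,
                          bias_percent=bias)


def load_paired_measurements(
    path: str | Path,
    role_a: str,
    role_b: str,
    gold_role: str | None = None,
) -> dict[str, PairedMeasurements]:
    """Read a long-format measurement CSV into per-parameter pairs.

    Expected columns: ``case_id,parameter,role,value``.  ``role_a`` and
    ``role_b`` select the two measurement series (e.g. ``reader1`` and
    ``reader2``, or ``reader1`` and ``automated``); cases missing either
    role for a parameter are dropped.  ``gold_role`` marks one role as the
    gold standard for bias computation.
    """
    df = pd.read_csv(path)
    required = {"case_id", "parameter", "role", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"measurement table missing column(s) {sorted(missing)}")
    out: dict[str, PairedMeasurements] = {}
    for parameter, sub in df.groupby("parameter"):
        wide = sub.pivot_table(index="case_id", columns="role", values="value")
        if role_a not in wide.columns or role_b not in wide.columns:
            continue
        wide = wide[[role_a, role_b]].dropna()
        if wide.empty:
            continue
        roles = (
            "gold" if role_a == gold_role else "reader",
            "gold" if role_b == gold_role else "reader",
        )
        out[str(parameter)] = PairedMeasurements(
            parameter=str(parameter),
            pairs=tuple(map(tuple, wide.to_numpy())),
            roles=roles,
        )
    return out


def agreement_table(
    datasets: Sequence[PairedMeasurements],
    icc_form: str = "absolute",
    bias_mode: str = "per_pair",
) -> pd.DataFrame:
    """Per-parameter agreement summary (ICC, RPC, bias %)."""
    rows = []
    for data in datasets:
        st = agreement_stats(data, icc_form=icc_form, bias_mode=bias_mode)
        rows.append({
            "parameter": data.parameter,
            "n_pairs": len(data.pairs),
            "icc": st.icc,
            "rpc": st.rpc,
            "bias_percent": st.bias_percent,
        })
    return pd.DataFrame(rows)
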