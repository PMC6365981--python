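"""End-to-end orchestration: meta-analysis reports and cohort runs.

A run is driven by a YAML config validated up front and copied verbatim
into ``provenance.json`` next to the outputs, together with the package
version and the master seed — enough to re-run bit-identically.

``run_meta`` chains study-table loading, per-grouping pooling, omnibus and
pairwise tests and target-region derivation.  ``run_cohort`` chains, per
case, CBF quantification (when raw ASL volumes are supplied), square-ROI
sampling and grey-matter normalisation; then cohort-level reader-agreement
simulation/ingestion, ROC thresholds, flowchart classification and the
combined logistic model.  Per-case failures are isolated and tallied; a
run fails only when every case fails.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import agreement as agr
from . import classify, meta, roi, synth
from .quant import AslParams, load_mask, load_nifti, quantify_cbf

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is malformed."""


def load_config(path: str | Path) -> dict:
    """Read and minimally validate a YAML run config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        config = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(config, dict):
        raise ConfigError("config must be a YAML mapping")
    return config


def _write_provenance(out_dir: Path, config: dict, seed: int | None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "provenance.json").write_text(json.dumps({
        "package": "tumourgrade",
        "version": __version__,
        "seed": seed,
        "config": config,
    }, indent=2, default=str))


def run_meta(config: dict, out_dir: str | Path) -> dict:
    """Meta-analysis over a study table; writes CSV + JSON reports."""
    out = Path(out_dir)
    table = config.get("study_table")  # None -> bundled fixture
    if table is not None and not Path(table).exists():
        raise ConfigError(f"study table not found: {table}")
    records = meta.load_study_table(table)
    report = meta.meta_report(
        records,
        min_patients=int(config.get("min_patients", 2)),
        tau2_share=config.get("tau2_share", "group"),
    )
    _write_provenance(out, config, None)
    meta.write_meta_report(report, out)
    log.info("meta run complete: %d studies", report["n_studies"])
    return report


# ---------------------------------------------------------------------------
# Cohort runs

def _asl_params(config: dict) -> AslParams:
    overrides = config.get("asl_params", {}) or {}
    return replace(AslParams(), **overrides)


def _synthetic_cases(config: dict, seed: int) -> list[dict]:
    """Generate a two-class phantom batch from the config's synthetic block.

    Per-class focus intensities emulate the clinical contrast: low-grade
    tumours keep ADC near normal tissue and modest perfusion; high-grade
    tumours carry a markedly low-ADC focus and a hot CBF focus.
    """
    block = config.get("synthetic") or {}
    n_low = int(block.get("n_low", 12))
    n_high = int(block.get("n_high", 12))
    noise_adc = float(block.get("noise_sd_adc", 0.05e-3))
    noise_cbf = float(block.get("noise_sd_cbf", 3.0))
    rng = np.random.default_rng(seed)
    focus = {
        "low": {"adc": (1.05e-3, 0.05e-3), "cbf": (50.0, 8.0)},
        "high": {"adc": (0.62e-3, 0.06e-3), "cbf": (115.0, 12.0)},
    }
    cases = []
    for grade, n in (("low", n_low), ("high", n_high)):
        for i in range(n):
            adc_mu, adc_sd = focus[grade]["adc"]
            cbf_mu, cbf_sd = focus[grade]["cbf"]
            spec = synth.PhantomSpec(
                adc_focus_value=float(np.clip(rng.normal(adc_mu, adc_sd),
                                              0.3e-3, 1.09e-3)),
                cbf_focus_value=float(max(rng.normal(cbf_mu, cbf_sd), 41.0)),
                noise_sd_adc=noise_adc,
                noise_sd_cbf=noise_cbf,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cases.append({
                "case_id": f"{grade}_{i:03d}",
                "grade": grade,
                "subtype": f"synthetic_{grade}_grade",
                "phantom_spec": spec,
            })
    return cases


def _load_case_volumes(case: dict, params: AslParams) -> dict:
    """Resolve one case's volumes from a phantom spec or NIfTI paths."""
    if "phantom_spec" in case:
        ph = synth.gen_phantom(case["phantom_spec"], params)
        # quantify CBF from the raw ASL volumes, exercising the full chain
        cbf = quantify_cbf(ph["delta_m"], ph["m0"], params)
        noise = ph["cbf"].values - ph["cbf_noiseless"].values
        cbf = replace(cbf, values=cbf.values + noise)
        return {"adc": ph["adc"], "cbf": cbf,
                "mask": ph["tumour_mask"], "gm": ph["gm_mask"]}
    vols = {"adc": load_nifti(case["adc"], units="mm2/s")}
    if "delta_m" in case and "m0" in case:
        vols["cbf"] = quantify_cbf(load_nifti(case["delta_m"]),
                                   load_nifti(case["m0"]), params)
    elif "cbf" in case:
        vols["cbf"] = load_nifti(case["cbf"], units="ml/100g/min")
    else:
        vols["cbf"] = None
    vols["mask"] = load_mask(case["mask"])
    vols["gm"] = load_mask(case["gm"]) if case.get("gm") else None
    return vols


def run_cohort(config: dict, out_dir: str | Path) -> dict:
    """Quantify, sample, and classify a cohort of cases.

    Writes ``measurements.csv``, ``agreement.csv`` (when reader data are
    simulated or supplied), ``classification.json``, per-case
    ``predictions.csv`` and ``provenance.json``.
    """
    out = Path(out_dir)
    seed = int(config.get("seed", 0))
    params = _asl_params(config)
    areas = [float(a) for a in config.get("roi_areas", [50.0])]
    primary_area = float(config.get("primary_roi_area", areas[0]))
    criterion = config.get("roc_criterion", "youden")
    exclude = tuple(config.get("exclude_subtypes",
                               classify.DEFAULT_EXCLUDED_SUBTYPES))

    if config.get("synthetic") is not None:
        cases = _synthetic_cases(config, seed)
    elif config.get("cases"):
        cases = list(config["cases"])
    else:
        raise ConfigError("config needs a 'synthetic' block or a 'cases' list")

    _write_provenance(out, config, seed)
    rows, failures = [], {}
    for case in cases:
        cid = str(case.get("case_id", f"case{len(rows)}"))
        try:
            vols = _load_case_volumes(case, params)
            sweep = roi.roi_size_sweep(vols["adc"], vols["cbf"], vols["mask"],
                                       vols["gm"], areas=areas)
            for area, m in sweep.items():
                if m is None:
                    continue
                row = roi.measurements_to_row(cid, m)
                row["grade"] = case.get("grade")
                row["subtype"] = case.get("subtype")
                rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            log.warning("case %s failed: %s", cid, exc)
            failures[cid] = str(exc)
    if not rows:
        raise RuntimeError(f"all {len(cases)} case(s) failed: {failures}")

    measurements = pd.DataFrame(rows)
    measurements.to_csv(out / "measurements.csv", index=False)

    primary = measurements[measurements["area_mm2"] == primary_area].copy()
    report: dict = {"n_cases": int(primary["case_id"].nunique()),
                    "n_failed": len(failures), "failures": failures,
                    "roi_areas": areas, "primary_roi_area": primary_area}

    # simulated reader agreement against the automated gold standard
    reader_cfg = config.get("readers")
    if reader_cfg:
        pairs = []
        for offset, parameter in enumerate(
            ("adc_roi_mean", "adc_roi_min", "ncbf_roi_max")
        ):
            truth = primary[parameter].dropna().to_numpy()
            if truth.size < 2:
                continue
            pairs.append(synth.gen_reader_pairs(
                truth,
                bias_fraction=float(reader_cfg.get("bias_fraction", 0.1)),
                noise_sd=float(reader_cfg.get("noise_frac", 0.1))
                * float(np.mean(np.abs(truth))),
                seed=seed + 1000 + offset,
                parameter=parameter,
            ))
        if pairs:
            table = agr.agreement_table(pairs)
            table.to_csv(out / "agreement.csv", index=False)
            report["agreement"] = table.to_dict(orient="records")

    labelled = primary.dropna(subset=["grade"]) if "grade" in primary else primary
    if "grade" in labelled.columns and labelled["grade"].nunique() == 2:
        cohort = classify.filter_cohort(labelled, exclude_subtypes=exclude)
        y = (cohort["grade"] == "high").to_numpy()
        roc_block = {}
        for parameter in ("adc_roi_mean", "adc_roi_min", "ncbf_roi_max"):
            vals = cohort[parameter]
            if vals.isna().any() or len(vals) == 0:
                continue
            direction = ("low_is_high_grade"
                         if parameter in classify.LOW_IS_HIGH_GRADE
                         else "high_is_high_grade")
            r = classify.roc_threshold(vals.to_numpy(), y, direction,
                                       criterion=criterion)
            roc_block[parameter] = asdict(r)
        report["roc"] = roc_block

        flow = [classify.classify_flowchart(
            {p: row[p] for p in classify.FLOWCHART_THRESHOLDS
             if pd.notna(row.get(p))}, subtype=row.get("subtype"))
            for _, row in cohort.iterrows()]
        acc = {}
        for parameter in classify.FLOWCHART_THRESHOLDS:
            verdicts = [f.get(parameter) for f in flow]
            ok = [v == g for v, g in zip(verdicts, cohort["grade"]) if v]
            if ok:
                acc[parameter] = float(np.mean(ok))
        report["flowchart_accuracy"] = acc

        try:
            model = classify.fit_logistic_grade(cohort)
            preds, summary = classify.apply_model(model, cohort)
            preds.to_csv(out / "predictions.csv", index=False)
            report["logistic"] = {
                "intercept": model.intercept,
                "coefficients": model.coefficients,
                "fit_method": model.fit_method,
                "training_accuracy": model.training_accuracy,
                **summary,
            }
        except classify.SampleSizeError as exc:
            report["logistic"] = {"error": str(exc)}

    (out / "classification.json").write_text(json.dumps(report, indent=2))
    log.info("cohort run complete: %d case(s), %d failure(s)",
             report["n_cases"], len(failures))
    return report
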