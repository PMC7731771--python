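"""End-to-end orchestration: plans -> DVHs -> factors -> curve -> constraints.

``run_pipeline`` drives the whole chain on a synthetic cohort (or, through
the same configuration surface, on externally supplied NRRD plan files):
plan QA, isovolumetric factor extraction inside the targets and in the
20 mm shell, cohort curve aggregation, OAR-constraint conversion and the
re-irradiation safety check.  All outputs are CSV; every random draw
flows from the single configured seed, so a rerun with the same
configuration is byte-identical.
"""

from __future__ import annotations

import copy
import shutil
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import reference
from .constraints import (
    DoseConstraint,
    NIRSReference,
    convert_constraint,
    convert_prescription,
    normalize_organ,
    safety_check,
)
from .convert import (
    ConversionCurve,
    aggregate_conversion_curve,
    extract_oar_conversion_samples,
    extract_target_factor,
    lookup_factor,
    make_isodose_levels,
    percent_difference,
    samples_to_frame,
)
from .errors import ConfigurationError, PipelineError
from .fractionation import LQParams
from .io import read_constraint_table, read_reference_table, write_dose_grid, write_structure_mask
from .plan import evaluate_plan
from .synthetic import (
    CohortVariation,
    SyntheticCohort,
    SyntheticPlanSpec,
    calibrate_ground_truth,
    generate_cohort,
)
from .util import round_half_up

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "rbeconv_out",
    "n_fractions": 21,
    "prescriptions": {"CTV1": 3.0, "CTV2": 2.7},
    "cohort": {
        "n_patients": 20,
        "grid_shape": [64, 64, 64],
        "spacing_mm": [2.0, 2.0, 2.0],
        "ctv1_semi_axes_mm": [15.0, 15.0, 15.0],
        "ctv2_margin_mm": 5.0,
        "noise_sigma": 0.01,
        "ctv_scale_range": [0.85, 1.15],
        "falloff_lambda_range": [5.0, 7.0],
        "ripple_range": [0.0, 0.02],
    },
    "truth": {"anchors": None},  # None -> published shell-curve endpoint anchors
    "levels": {"d_max_total": 60.0, "d_min_total": 5.0, "step": 1.0},
    "shell_cohort": None,  # list of patient ids contributing to the shell curve; None = all
    "target_statistic": "median",
    "constraints": "builtin",
    "references": "builtin",
    "explicit_lem16": "builtin",
    "mode": "explicit",
    "alpha_beta": None,
    "n_target_fractions": 16,
    "safety_fraction": 0.70,
}


def load_config(config: str | Path | Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Merge a YAML file or mapping over the defaults (one level deep)."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    if config is None:
        return merged
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    for key, value in config.items():
        if key not in merged:
            raise ConfigurationError(f"unknown config key {key!r}")
        if isinstance(merged[key], dict) and isinstance(value, Mapping):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    shell_curve: ConversionCurve
    frames: dict[str, pd.DataFrame]
    output_dir: Path | None


def build_cohort(cfg: Mapping[str, Any]) -> SyntheticCohort:
    """Instantiate the synthetic cohort described by the configuration."""
    c = cfg["cohort"]
    anchors = cfg["truth"]["anchors"]
    truth = (calibrate_ground_truth(tuple(anchors[0]), tuple(anchors[1]))
             if anchors else calibrate_ground_truth())
    base = SyntheticPlanSpec(
        grid_shape=tuple(c["grid_shape"]),
        spacing_mm=tuple(c["spacing_mm"]),
        ctv1_semi_axes_mm=tuple(c["ctv1_semi_axes_mm"]),
        ctv2_margin_mm=float(c["ctv2_margin_mm"]),
        prescription_fraction_dose=float(cfg["prescriptions"]["CTV1"]),
        ctv2_fraction_dose=float(cfg["prescriptions"]["CTV2"]),
        n_fractions=int(cfg["n_fractions"]),
        noise_sigma=float(c["noise_sigma"]),
    )
    variation = CohortVariation(
        ctv_scale=tuple(c["ctv_scale_range"]),
        falloff_lambda_mm=tuple(c["falloff_lambda_range"]),
        ripple=tuple(c["ripple_range"]),
    )
    return generate_cohort(
        n_patients=int(c["n_patients"]),
        base_spec=base,
        variation=variation,
        truth=truth,
        seed=int(cfg["seed"]),
    )


def _constraint_inputs(cfg: Mapping[str, Any]):
    constraints = (list(reference.LEM_CONSTRAINTS_21FX)
                   if cfg["constraints"] == "builtin"
                   else read_constraint_table(cfg["constraints"]))
    refs = (list(reference.NIRS_REFERENCES_16FX)
            if cfg["references"] == "builtin"
            else read_reference_table(cfg["references"]))
    explicit = (dict(reference.LEM_CONSTRAINTS_16FX_EXPLICIT)
                if cfg["explicit_lem16"] == "builtin"
                else dict(cfg["explicit_lem16"] or {}))
    return constraints, refs, {normalize_organ(k): v for k, v in explicit.items()}


def run_pipeline(
    config: str | Path | Mapping[str, Any] | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run every stage and (optionally) write the CSV report bundle.

    Outputs: ``manifest.csv``, ``qa_report.csv``, ``samples.csv``,
    ``curve_shell.csv``, ``target_factors.csv`` (per-patient, presentation
    rounding), ``target_summary.csv`` (cohort means/CIs, MKM prescriptions
    and percent differences with the published comparison values),
    ``constraints_report.csv`` and ``safety_report.csv``.  A stage failure
    aborts with the failing stage named and leaves no partial outputs.
    """
    cfg = load_config(config)
    frames: dict[str, pd.DataFrame] = {}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
            raise PipelineError(name, exc) from exc

    cohort = stage("synthetic cohort generation", build_cohort, cfg)
    frames["manifest"] = pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "ctv1_semi_axes_mm": "x".join(f"{a:g}" for a in p.spec.ctv1_semi_axes_mm),
                "falloff_lambda_mm": p.spec.falloff_lambda_mm,
                "ripple": p.spec.ripple,
                "noise_sigma": p.spec.noise_sigma,
                "n_fractions": p.spec.n_fractions,
                "seed": p.spec.seed,
            }
            for p in cohort.patients
        ]
    )

    # --- plan QA ------------------------------------------------------------
    def qa():
        rows = []
        for p in cohort.patients:
            n = p.lem.n_fractions
            targets = [(p.masks["CTV1"], p.spec.prescription_fraction_dose * n)]
            if "CTV2" in p.masks:
                targets.append((p.masks["CTV2"], p.spec.ctv2_fraction_dose * n))
            oar_rules = []
            if "OAR" in p.masks and not p.masks["OAR"].is_empty:
                oar_rules.append((p.masks["OAR"], "Dmax", 45.0))
            report = evaluate_plan(p.lem, targets, oar_rules)
            for rec in report.to_rows():
                rows.append({"patient_id": p.patient_id, **rec})
        return pd.DataFrame(rows)

    frames["qa_report"] = stage("plan QA", qa)

    # --- factor extraction ----------------------------------------------------
    def extract():
        shell_members = cfg["shell_cohort"] or [p.patient_id for p in cohort.patients]
        levels = make_isodose_levels(
            d_max_total=float(cfg["levels"]["d_max_total"]),
            d_min_total=float(cfg["levels"]["d_min_total"]),
            step=float(cfg["levels"]["step"]),
            n_fractions=int(cfg["n_fractions"]),
        )
        samples = []
        for p in cohort.patients:
            for region, presc_key in (("CTV1", "CTV1"), ("CTV2", "CTV2")):
                if region not in p.masks:
                    continue
                s = extract_target_factor(
                    p.lem, p.mkm, p.masks[region],
                    float(cfg["prescriptions"][presc_key]),
                    statistic=cfg["target_statistic"],
                )
                if s is not None:
                    samples.append(s)
            if p.patient_id in shell_members:
                samples.extend(
                    extract_oar_conversion_samples(p.lem, p.mkm, p.masks["SHELL"], levels)
                )
        return samples

    samples = stage("factor extraction", extract)
    frames["samples"] = samples_to_frame(samples)

    # --- curve aggregation ----------------------------------------------------
    def aggregate():
        shell_curve = aggregate_conversion_curve(samples, region="SHELL")
        target_curves = {}
        for region in ("CTV1", "CTV2"):
            region_samples = [s for s in samples if s.region == region]
            if region_samples:
                target_curves[region] = aggregate_conversion_curve(region_samples)
        return shell_curve, target_curves

    shell_curve, target_curves = stage("curve aggregation", aggregate)
    frames["curve_shell"] = shell_curve.to_frame()

    # table-3-shaped per-patient factor report (presentation rounding)
    def target_report():
        by_patient: dict[str, dict[str, float]] = {}
        for s in samples:
            if s.region in ("CTV1", "CTV2"):
                by_patient.setdefault(s.patient_id, {})[s.region] = s.factor
        rows = []
        for pid in sorted(by_patient):
            f = by_patient[pid]
            rows.append(
                {
                    "patient_id": pid,
                    "ctv1_factor": round_half_up(f["CTV1"], 2) if "CTV1" in f else np.nan,
                    "ctv2_factor": round_half_up(f["CTV2"], 2) if "CTV2" in f else np.nan,
                }
            )
        return pd.DataFrame(rows)

    frames["target_factors"] = stage("target factor report", target_report)

    def target_summary():
        rows = []
        for region, curve in target_curves.items():
            presc = float(cfg["prescriptions"][region])
            mean = float(curve.mean_factors[0])
            rows.append(
                {
                    "region": region,
                    "prescription_fraction_Gy_RBE": presc,
                    "mean_factor": round_half_up(mean, 2),
                    "ci_low": round_half_up(float(curve.ci_low[0]), 2),
                    "ci_high": round_half_up(float(curve.ci_high[0]), 2),
                    "n_patients": int(curve.n_patients[0]),
                    "mkm_fraction_Gy_RBE": round_half_up(
                        convert_prescription(presc, mean), 2
                    ),
                    "percent_difference": round_half_up(percent_difference(mean), 2),
                    "published_comparison_percent":
                        reference.FOSSATI_PERCENT_DIFFERENCES.get(presc, np.nan),
                }
            )
        return pd.DataFrame(rows)

    frames["target_summary"] = stage("target summary", target_summary)

    # --- constraint conversion -----------------------------------------------
    def constraints_report():
        constraints, refs, explicit = _constraint_inputs(cfg)
        lq = LQParams(float(cfg["alpha_beta"])) if cfg["alpha_beta"] else None
        n_target = int(cfg["n_target_fractions"])
        converted, rows = [], []
        for c in constraints:
            organ = normalize_organ(c.organ)
            kwargs = {}
            if cfg["mode"] == "explicit":
                if organ not in explicit:
                    raise ConfigurationError(
                        f"explicit mode: no {n_target}-fraction LEM dose for {c.organ!r}"
                    )
                kwargs["explicit_dose"] = float(explicit[organ])
            mkm_c, audit = convert_constraint(
                c, n_target, shell_curve, lq=lq, mode=cfg["mode"],
                propagate_ci=True, **kwargs,
            )
            converted.append(mkm_c)
            ci = audit.mkm_total_ci
            rows.append(
                {
                    "organ": organ,
                    "metric": c.metric,
                    "lem_total_Gy_RBE": round_half_up(c.total_dose, 2),
                    "lem_n_fractions": c.n_fractions,
                    f"lem_{n_target}fx_Gy_RBE": round_half_up(audit.lem_total_at_target, 2),
                    f"mkm_{n_target}fx_Gy_RBE": round_half_up(audit.mkm_total, 2),
                    "mkm_ci_low": round_half_up(ci[0], 2) if ci else np.nan,
                    "mkm_ci_high": round_half_up(ci[1], 2) if ci else np.nan,
                    "conversion_factor": round_half_up(audit.factor, 2),
                    "mode": audit.mode,
                    "curve_clamped": audit.clamped,
                }
            )
        return converted, refs, pd.DataFrame(rows)

    converted, refs, frames["constraints_report"] = stage(
        "constraint conversion", constraints_report
    )

    # --- safety check ---------------------------------------------------------
    def safety():
        report = safety_check(converted, refs, float(cfg["safety_fraction"]))
        df = report.to_frame()
        for col in ("converted_mkm_Gy_RBE", "threshold_Gy_RBE", "margin_Gy_RBE"):
            df[col] = df[col].map(lambda x: round_half_up(x, 2))
        return df

    frames["safety_report"] = stage("re-irradiation safety check", safety)

    # --- report writing -------------------------------------------------------
    out_dir: Path | None = None
    if write:
        def write_all() -> Path:
            out = Path(cfg["output_dir"])
            out.mkdir(parents=True, exist_ok=True)
            staging = Path(tempfile.mkdtemp(prefix=".rbeconv_staging_", dir=out))
            try:
                for name, df in frames.items():
                    df.to_csv(staging / f"{name}.csv", index=False)
                for f in staging.iterdir():
                    shutil.move(str(f), out / f.name)
            finally:
                shutil.rmtree(staging, ignore_errors=True)
            return out

        out_dir = stage("report writing", write_all)

    return PipelineResult(cohort=cohort, shell_curve=shell_curve,
                          frames=frames, output_dir=out_dir)


def write_cohort_volumes(cohort: SyntheticCohort, directory: str | Path) -> pd.DataFrame:
    """Write every patient's paired grids and masks as NRRD files.

    Returns the file manifest (also written as ``plan_manifest.csv``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.patients:
        files = {}
        for tag, grid in (("lem", p.lem), ("mkm", p.mkm)):
            path = directory / f"{p.patient_id}_{tag}.nrrd"
            write_dose_grid(grid, path)
            files[tag] = path.name
        for name, mask in p.masks.items():
            path = directory / f"{p.patient_id}_{name.lower()}.nrrd"
            write_structure_mask(mask, path)
            files[name] = path.name
        rows.append({"patient_id": p.patient_id, "seed": p.spec.seed, **files})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "plan_manifest.csv", index=False)
    return manifest
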