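"""File formats, configuration and the staged pipeline runner.

Everything on disk is comma-separated UTF-8 with one header row (decimal
point, no locale variants) or JSON.  Concentrations are ug/kg for
sample-level quantities and ug/L for calibration levels; column names carry
the unit where mixing is plausible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import MODEL_TERMS, DesignTable, FactorSpec, generate_bbd
from .exceptions import DependencyError, EmptyTableError, SchemaError
from .model import QuadraticModel, ResponseSurfaceModel
from .optimize import optimize_in_cube
from .simulate import default_truth, simulate_quant_assets, simulate_recovery_experiment
from .validation import ComplianceRule, compliant_count, validation_summary

__all__ = [
    "SCHEMAS",
    "PipelineConfig",
    "read_table",
    "model_to_json",
    "model_from_json",
    "run_pipeline",
]

#: Required columns per input kind; design/response additionally carry one
#: column per factor, validated against the configured factor names.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "design": ("run_id", "point_type"),
    "response": ("run_id", "point_type", "y"),
    "recovery": ("analyte", "matrix", "spike_level", "day", "replicate", "measured"),
    "calibration": ("analyte", "context", "level_ugl", "response"),
}

_NUMERIC = {
    "design": (),
    "response": ("y",),
    "recovery": ("spike_level", "day", "replicate", "measured"),
    "calibration": ("level_ugl", "response"),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate one delimited input file.

    Header matching is case-insensitive; a missing column raises
    :class:`SchemaError` naming it, an unparseable numeric raises a
    row-addressed error, an empty data section raises
    :class:`EmptyTableError`.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    frame.columns = [c.strip().lower() for c in frame.columns]
    for col in SCHEMAS[schema]:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")
    if frame.empty:
        raise EmptyTableError(f"{path.name}: no data rows")
    numeric = set(_NUMERIC[schema]) | (
        set(frame.columns) - set(SCHEMAS[schema]) if schema in ("design", "response") else set()
    )
    for col in numeric:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[parsed.isna() & frame[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path.name}: column {col!r}, row {bad[0] + 2}: "
                f"cannot parse {frame.loc[bad[0], col]!r} as a number"
            )
        frame[col] = parsed
    return frame


def model_to_json(model: QuadraticModel, path=None) -> dict:
    """Serialise a fitted surface as {"terms": {name: coefficient}}."""
    payload = {"terms": dict(zip(MODEL_TERMS, (float(v) for v in model.params)))}
    if path is not None:
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return payload


def model_from_json(source) -> QuadraticModel:
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    terms = source["terms"]
    return QuadraticModel.from_params([terms[t] for t in MODEL_TERMS])


_CONFIG_KEYS = {
    "factors",
    "n_center",
    "vl_ugkg",
    "window_lower",
    "window_upper",
    "rounding",
    "seed",
    "n_analytes",
    "n_replicates",
    "response_path",
    "recovery_path",
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    Loaded from YAML with strict key checking — an unknown key is an error,
    not a silent no-op — and logged alongside the seed on every run so a
    report is reproducible from its own metadata.
    """

    factors: tuple[FactorSpec, FactorSpec, FactorSpec]
    n_center: int = 5
    vl_ugkg: float = 50.0
    window_lower: float = 80.0
    window_upper: float = 110.0
    rounding: str = "truncate"
    seed: int = 0
    n_analytes: int = 43
    n_replicates: int = 3
    response_path: str | None = None
    recovery_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise SchemaError("config must be a YAML mapping")
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "factors" not in raw:
            raise SchemaError("config missing 'factors'")
        factors = tuple(
            FactorSpec(
                name=f["name"],
                actual_low=float(f["low_mg"]),
                actual_high=float(f["high_mg"]),
                actual_center=float(f["center_mg"]) if "center_mg" in f else None,
            )
            for f in raw.pop("factors")
        )
        return cls(factors=factors, **raw)

    @property
    def rule(self) -> ComplianceRule:
        return ComplianceRule(lower=self.window_lower, upper=self.window_upper)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


_STAGE_ORDER = ("design", "simulate", "fit", "anova", "optimize", "validate")


def run_pipeline(config: PipelineConfig, stages=None, out_dir=".") -> dict:
    """Run the requested stages in dependency order and write a JSON report.

    Stages: design -> (simulate) -> fit -> anova/optimize, validate.  A stage
    whose inputs are unavailable raises :class:`DependencyError` naming what
    is missing.  The report (``report.json``) embeds the resolved
    configuration, the seed, and a digest of every file written, and is
    byte-identical across runs with the same config and seed.
    """
    stages = set(_STAGE_ORDER) if stages is None else set(stages)
    unknown = stages - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": {
            "factors": [
                {"name": s.name, "low_mg": s.actual_low, "center_mg": s.actual_center,
                 "high_mg": s.actual_high}
                for s in config.factors
            ],
            "n_center": config.n_center,
            "vl_ugkg": config.vl_ugkg,
            "window": [config.window_lower, config.window_upper],
            "rounding": config.rounding,
            "seed": config.seed,
        },
        "stages": {},
        "log": [],
    }

    def _log(stage: str, path: Path) -> None:
        report["log"].append(f"{stage}: wrote {path.name} sha256:{_digest(path)}")

    design: DesignTable | None = None
    response = None
    records = None
    curves = None
    results = None

    if "design" in stages or stages & {"simulate", "fit", "anova", "optimize"}:
        design = generate_bbd(config.factors, n_center=config.n_center)
        if "design" in stages:
            p = out / "design.csv"
            design.to_csv(p)
            _log("design", p)
            report["stages"]["design"] = {
                "n_runs": len(design),
                "n_center": design.n_center,
                "factors": design.factor_names,
            }

    if "simulate" in stages:
        truth = default_truth(n_analytes=config.n_analytes, seed=config.seed)
        records = simulate_recovery_experiment(
            truth, design, n_replicates=config.n_replicates, seed=config.seed
        )
        counts = records.groupby("run_id", sort=True).apply(
            lambda g: compliant_count(g, config.rule), include_groups=False
        )
        response = counts.reindex(design.runs["run_id"]).to_numpy(dtype=float)
        curves_by_name, quant_records = simulate_quant_assets(
            truth, levels=[0.5, 1, 5, 10, 50, 100], seed=config.seed + 1
        )
        curves = {
            (name, truth.matrix): pair for name, pair in curves_by_name.items()
        }
        records_all = pd.concat([records.drop(columns=["run_id"]), quant_records])
        p = out / "recovery.csv"
        records_all.to_csv(p, index=False)
        _log("simulate", p)
        p = out / "response.csv"
        resp_table = design.runs.copy()
        resp_table["y"] = response
        resp_table.to_csv(p, index=False)
        _log("simulate", p)
        report["stages"]["simulate"] = {
            "n_analytes": truth.n_analytes,
            "response": [float(v) for v in response],
        }
        records = quant_records  # validation uses the 0.2*VL replicate sets

    if stages & {"fit", "anova", "optimize"}:
        if response is None:
            if config.response_path is None:
                raise DependencyError(
                    "fit stage needs a response: run the simulate stage or set response_path"
                )
            resp_table = read_table(config.response_path, "response")
            response = resp_table["y"].to_numpy(dtype=float)
        results = ResponseSurfaceModel(design, response).fit()
        if "fit" in stages:
            p = out / "model.json"
            model_to_json(results.model, p)
            _log("fit", p)
            report["stages"]["fit"] = model_to_json(results.model)

    if "anova" in stages:
        table = results.anova().to_frame()
        p = out / "anova.csv"
        table.to_csv(p, index=False, float_format="%.6g")
        _log("anova", p)
        adq = results.adequacy()
        report["stages"]["anova"] = {
            "table": json.loads(table.to_json(orient="records")),
            "r2": adq.r2,
            "adj_r2": adq.adj_r2,
            "pred_r2": adq.pred_r2,
            "adeq_precision": adq.adeq_precision,
        }

    if "optimize" in stages:
        opt = optimize_in_cube(
            results.model, specs=config.factors, rounding=config.rounding
        )
        payload = {
            "coded": [float(v) for v in opt.coded],
            "actual_mg": [float(v) for v in opt.actual],
            "predicted_response": opt.predicted_response,
            "predicted_count": opt.predicted_count,
            "on_boundary": opt.on_boundary,
        }
        p = out / "optimum.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        _log("optimize", p)
        report["stages"]["optimize"] = payload

    if "validate" in stages:
        if records is None:
            if config.recovery_path is None:
                raise DependencyError(
                    "validate stage needs recovery records: run the simulate "
                    "stage or set recovery_path"
                )
            records = read_table(config.recovery_path, "recovery")
        summary = validation_summary(
            records, curves=curves, rule=config.rule, vl=config.vl_ugkg
        )
        p = out / "validation_summary.csv"
        summary.to_csv(p, index=False, float_format="%.6g")
        _log("validate", p)
        report["stages"]["validate"] = {
            "n_analytes": int(summary["analyte"].nunique()),
            "cc_alpha_range": [
                float(np.nanmin(summary["cc_alpha"])),
                float(np.nanmax(summary["cc_alpha"])),
            ],
            "cc_beta_range": [
                float(np.nanmin(summary["cc_beta"])),
                float(np.nanmax(summary["cc_beta"])),
            ],
        }

    p = out / "report.json"
    p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
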