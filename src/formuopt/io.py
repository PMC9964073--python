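"""Shared CSV dialects, run configuration and the pipeline driver.

The canonical interchange format is UTF-8 CSV with a header row, '.' decimal
separator, round-trip lossless at 12 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TableSchemaError", "RunConfig", "read_table", "write_table", "run_pipeline"]

FLOAT_FORMAT = "%.12g"


class TableSchemaError(ValueError):
    """Raised with row/column context when a CSV does not match its schema."""


def read_table(path, schema: dict[str, type] | None = None) -> pd.DataFrame:
    """Read a CSV table, optionally coercing/validating columns.

    ``schema`` maps required column names to types (float, int or str).
    Violations raise :class:`TableSchemaError` naming the offending row
    (1-based, excluding the header) and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    if frame.empty and len(frame.columns) == 0:
        raise TableSchemaError(f"{path}: empty table")
    if schema is None:
        return frame
    missing = [c for c in schema if c not in frame.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing columns {missing}")
    for col, typ in schema.items():
        if typ in (float, int):
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise TableSchemaError(
                    f"{path}: malformed numeric value {frame.loc[bad[0], col]!r} "
                    f"in column {col!r}, row {bad[0] + 1}"
                )
            frame[col] = coerced.astype(float if typ is float else "Int64")
        else:
            frame[col] = frame[col].astype(str)
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


_KNOWN_KEYS = {
    "stages",
    "seed",
    "design_csv",
    "responses_csv",
    "responses",
    "scale",
    "block_handling",
    "bounds",
    "grid_density",
    "desirability",
    "out_dir",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    stages: list[str]
    seed: int
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" not in raw:
            raise ValueError("config requires 'stages'")
        if "seed" not in raw:
            raise ValueError("config requires an explicit 'seed'")
        params = {k: v for k, v in raw.items() if k not in ("stages", "seed")}
        return cls(stages=list(raw["stages"]), seed=int(raw["seed"]), params=params)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in order and return a structured report.

    Supported stages: ``fit`` (quadratic RSM per response) and ``desirability``
    (multi-response optimization over the fitted surfaces).  The report JSON
    is also written to ``out_dir`` when given.
    """
    from . import __version__
    from .desirability import DesirabilitySpec, ResponseGoal, optimize_desirability
    from .oracle import ccd_fixture_responses
    from .rsm import fit_quadratic

    report: dict = {"config": {"stages": config.stages, "seed": config.seed, **config.params},
                    "version": __version__, "stages": {}}
    models = {}
    try:
        if "fit" in config.stages:
            if config.params.get("design_csv"):
                from .design import ResponseTable, design_from_frame

                design = design_from_frame(read_table(config.params["design_csv"]))
                resp_frame = read_table(config.params["responses_csv"]).set_index("code")
                resp = ResponseTable(resp_frame)
            else:
                design, resp = ccd_fixture_responses()
            fitted = {}
            for name in config.params.get("responses", ["Y1", "Y2"]):
                model = fit_quadratic(
                    design,
                    resp,
                    name,
                    scale=config.params.get("scale", "actual"),
                    block_handling=config.params.get("block_handling", "fixed_effect"),
                )
                models[name] = model
                fitted[name] = {
                    "intercept": model.intercept,
                    "linear": list(model.linear),
                    "interaction": list(model.interaction),
                    "quadratic": list(model.quadratic),
                }
            report["stages"]["fit"] = {"coefficients": fitted}
        if "desirability" in config.stages:
            if not models:
                raise ValueError("desirability stage requires a prior fit stage")
            spec_raw = config.params.get(
                "desirability", {"Y1": {"lower_bound": 70.0}, "Y2": {"lower_bound": 40.0}}
            )
            bounds = config.params.get("bounds", [[0.5, 1.5], [0.0, 0.2], [0.5, 1.5]])
            goals = {}
            for name, g in spec_raw.items():
                target = g.get("target")
                if target is None:
                    # default target: max predicted value over the box (kept
                    # strictly above the floor so the ramp stays well-defined)
                    axes = [np.linspace(lo, hi, 21) for lo, hi in bounds]
                    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
                    target = max(
                        float(np.max(models[name].predict(grid))),
                        float(g["lower_bound"]) + 1e-6,
                    )
                goals[name] = ResponseGoal(
                    lower_bound=float(g["lower_bound"]),
                    target=float(target),
                    weight=float(g.get("weight", 1.0)),
                )
            result = optimize_desirability(
                models,
                DesirabilitySpec(goals),
                bounds,
                grid_density=int(config.params.get("grid_density", 51)),
            )
            report["stages"]["desirability"] = {
                "best_point": [float(v) for v in result.best_point],
                "predicted_responses": result.predicted_responses,
                "composite_desirability": result.composite_desirability,
            }
    except Exception as exc:
        report["status"] = "failed"
        report["error"] = f"{type(exc).__name__}: {exc}"
        return report
    report["status"] = "ok"
    out_dir = config.params.get("out_dir")
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
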