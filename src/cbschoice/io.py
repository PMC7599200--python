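"""CSV ingestion, fit-report serialization and run configuration.

The CSV schema is ``amount1, attr1, amount2, attr2, choice`` with a header
row; attributes are delays in days (ITC) or win probabilities (RC) and
``choice`` is 1 or 2.  Fit reports are JSON (indented, so both machine- and
human-readable) carrying the model code, parameters, sigma, likelihood,
requested metrics, diagnostic flags, seeds and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .fitting import ChoiceDataset, FitConfig, FitResult
from .models import CBSSpec

__all__ = [
    "SchemaError",
    "ValidationError",
    "COLUMNS",
    "read_choice_csv",
    "write_choice_csv",
    "write_fit_report",
    "read_fit_report",
    "load_config",
    "config_hash",
]

COLUMNS = ("amount1", "attr1", "amount2", "attr2", "choice")


class SchemaError(ValueError):
    """The file does not have the expected columns."""


class ValidationError(ValueError):
    """A row violates the task's domain constraints."""


def read_choice_csv(path, task: str) -> ChoiceDataset:
    """Read trial-level choices, validating every row (reported by line)."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}; "
                          f"expected header {', '.join(COLUMNS)}")
    problems = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        if not np.isfinite(row[list(COLUMNS)]).all():
            problems.append(f"line {line}: non-numeric or missing value")
            continue
        if row["amount1"] <= 0 or row["amount2"] <= 0:
            problems.append(f"line {line}: amounts must be positive")
        if int(row["choice"]) not in (1, 2):
            problems.append(f"line {line}: choice must be 1 or 2")
        for col in ("attr1", "attr2"):
            v = row[col]
            if task == "ITC" and v < 0:
                problems.append(f"line {line}: {col}={v} (delays must be >= 0)")
            if task == "RC" and not 0 <= v <= 1:
                problems.append(f"line {line}: {col}={v} (probabilities must be in [0, 1])")
    if problems:
        raise ValidationError(f"{path.name}: " + "; ".join(problems))
    return ChoiceDataset.from_arrays(
        task, frame["amount1"].to_numpy(float), frame["attr1"].to_numpy(float),
        frame["amount2"].to_numpy(float), frame["attr2"].to_numpy(float),
        frame["choice"].to_numpy(int), label=path.stem,
    )


def write_choice_csv(data: ChoiceDataset, path) -> None:
    arr = data.arrays()
    frame = pd.DataFrame({
        "amount1": arr["a1"], "attr1": arr["x1"],
        "amount2": arr["a2"], "attr2": arr["x2"], "choice": arr["choice"],
    })
    frame.to_csv(path, index=False)


def _spec_block(spec) -> dict:
    if isinstance(spec, CBSSpec):
        return {"kind": "CBS", "task": spec.task, "n_pieces": spec.n_pieces,
                "x_scale": spec.x_scale}
    return {"kind": "parametric", "task": spec.task, "family": spec.code}


def config_hash(config: FitConfig) -> str:
    payload = {k: v for k, v in asdict(config).items() if k != "extra_starts"}
    payload["extra_starts"] = [list(np.asarray(s, dtype=float))
                               for s in config.extra_starts]
    blob = json.dumps(payload, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_fit_report(fit: FitResult, metrics: Mapping | None, path,
                     config: FitConfig | None = None) -> dict:
    """Serialize a fit (+ optional metrics) to an indented JSON report."""
    report = {
        "model": fit.code,
        "spec": _spec_block(fit.spec),
        "parameters": fit.params,
        "sigma": fit.sigma,
        "log_likelihood": fit.log_likelihood,
        "n_trials": fit.n_trials,
        "n_starts": fit.n_starts,
        "best_start": fit.best_start,
        "converged": fit.converged,
        "flags": list(fit.flags),
        "start_seeds": list(fit.start_seeds),
        "metrics": _jsonable(metrics) if metrics else {},
    }
    if config is not None:
        report["config_hash"] = config_hash(config)
        report["seed"] = config.seed
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
    return report


def read_fit_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    if isinstance(obj, FitResult):
        return {"model": obj.code, "log_likelihood": obj.log_likelihood}
    return obj


def load_config(path) -> dict:
    """Load a YAML/JSON run-configuration file."""
    with open(path) as fh:
        return yaml.safe_load(fh)
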