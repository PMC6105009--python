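"""Readers/writers for session TSVs, priors YAML, and result manifests.

One session = one tidy TSV, one row per trial, columns: subject_id, trial,
color, shape, outcome, relevant_dimension, rewarded_manifestation, expected,
rt_ms, responded. Trial indices are 1-based in all files. A leading
``# config: {...}`` comment line carries the generating TaskConfig so that
sessions round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from relsal.task import (
    COLOR_MANIFESTATIONS,
    DIMENSIONS,
    OUTCOMES,
    SHAPE_MANIFESTATIONS,
    TaskConfig,
    TaskSequence,
)

SESSION_COLUMNS = [
    "subject_id",
    "trial",
    "color",
    "shape",
    "outcome",
    "relevant_dimension",
    "rewarded_manifestation",
    "expected",
    "rt_ms",
    "responded",
]


class SchemaError(ValueError):
    """A session file violates the documented column schema."""


def load_session(path) -> tuple[TaskSequence, pd.DataFrame]:
    """Load and validate one session TSV into (TaskSequence, behavior table).

    Schema violations are reported with 1-based data row numbers.
    """
    path = Path(path)
    config = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config:"):
        config = TaskConfig(**json.loads(first.split(":", 1)[1]))
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"subject_id": str})

    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    errors = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        if row.color not in COLOR_MANIFESTATIONS:
            errors.append(f"row {row_no}: bad color {row.color!r}")
        if row.shape not in SHAPE_MANIFESTATIONS:
            errors.append(f"row {row_no}: bad shape {row.shape!r}")
        if row.outcome not in OUTCOMES:
            errors.append(f"row {row_no}: bad outcome {row.outcome!r}")
        if row.relevant_dimension not in DIMENSIONS:
            errors.append(f"row {row_no}: bad relevant_dimension {row.relevant_dimension!r}")
        try:
            t = int(row.trial)
            if not 1 <= t <= len(df):
                errors.append(f"row {row_no}: trial index {t} out of range 1..{len(df)}")
        except (TypeError, ValueError):
            errors.append(f"row {row_no}: non-integer trial index {row.trial!r}")
        if not _is_number_or_missing(row.rt_ms):
            errors.append(f"row {row_no}: non-numeric rt_ms {row.rt_ms!r}")
        if errors and len(errors) >= 50:
            break
    if errors:
        raise SchemaError("; ".join(errors))

    df = df.sort_values("trial").reset_index(drop=True)
    if config is None:
        # reconstruct what the file alone supports; exactness flags unknowable
        n = len(df)
        switch = int((df["relevant_dimension"] != df["relevant_dimension"].iloc[0]).idxmax())
        config = TaskConfig(
            n_trials=n,
            switch_trial=switch if switch > 0 else n,
            first_relevant_dimension=str(df["relevant_dimension"].iloc[0]),
        )
    trials = df[
        [
            "trial",
            "color",
            "shape",
            "outcome",
            "relevant_dimension",
            "rewarded_manifestation",
            "expected",
        ]
    ].copy()
    trials["trial"] = trials["trial"].astype(np.int64)
    schedule_rows = []
    for b in range(config.n_trials // config.block_length):
        first = trials.iloc[b * config.block_length]
        schedule_rows.append(
            {
                "block": b + 1,
                "first_trial": b * config.block_length + 1,
                "relevant_dimension": first["relevant_dimension"],
                "rewarded_manifestation": first["rewarded_manifestation"],
            }
        )
    task = TaskSequence(config=config, trials=trials, schedule=pd.DataFrame(schedule_rows))
    behavior = pd.DataFrame(
        {
            "trial": trials["trial"],
            "rt_ms": pd.to_numeric(df["rt_ms"], errors="coerce"),
            "responded": df["responded"].astype(bool),
        }
    )
    return task, behavior


def _is_number_or_missing(x) -> bool:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return True
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def save_results(results: dict, out_dir) -> dict:
    """Write result artifacts plus a checksummed manifest.

    ``results`` maps relative file names to DataFrames (written as TSV) or
    JSON-serializable objects (written as JSON). The manifest enumerates
    every written file with its SHA-256 checksum; identical inputs produce
    identical manifests except for the timestamp.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {}
    for name, obj in sorted(results.items()):
        p = out_dir / name
        p.parent.mkdir(parents=True, exist_ok=True)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(p, sep="\t", index=True)
        else:
            with open(p, "w") as fh:
                json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        entries[name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "files": entries,
        "content_hash": hashlib.sha256(
            json.dumps(entries, sort_keys=True).encode()
        ).hexdigest(),
        "package_version": _version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _version() -> str:
    import relsal

    return relsal.__version__


def load_priors(path) -> dict:
    """Load a priors YAML: ``{param: {transform, mean, var}}`` entries."""
    import yaml

    from relsal.inference import ParamPrior, default_priors

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    priors = default_priors()
    for name, spec in raw.items():
        if name not in priors:
            raise KeyError(f"unknown parameter {name!r} in priors file")
        priors[name] = ParamPrior(
            transform=spec.get("transform", priors[name].transform),
            mean=float(spec["mean"]),
            var=float(spec["var"]),
        )
    return priors
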