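"""Cohort CSV schema, run configuration and report bundles.

The canonical cohort CSV has the header

    id, lens_model, age, sex, al_mm, k1_d, k2_d, acd_mm, iol_power_d, postop_se_d

(extra columns are preserved; unknown *required* columns are a schema
error).  A benchmark run emits a deterministic file set — prediction
records, metric tables in CSV and JSON, the statistical test table, the
serialized run configuration and a plain-text summary — so any published
result can be regenerated from its embedded config and seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .cohort import REQUIRED_COLUMNS, validate_cohort
from .errors import CohortSchemaError, CohortValidationError
from .evaluation import CVConfig

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "config_to_yaml",
    "config_from_yaml",
    "run_report",
]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; row failures carry CSV line numbers."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"{path.name}: missing required column(s) {missing}; "
            f"expected header {list(REQUIRED_COLUMNS)}"
        )
    failures = validate_cohort(df)
    if failures:
        # +2: one for the header line, one for 1-based numbering
        raise CohortValidationError([(idx + 2, msg) for idx, msg in failures])
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort with the canonical columns first (extras preserved)."""
    extras = [c for c in cohort.columns if c not in REQUIRED_COLUMNS]
    cohort[list(REQUIRED_COLUMNS) + extras].to_csv(path, index=False)


def config_to_yaml(config: CVConfig, path=None) -> str:
    payload = dataclasses.asdict(config)
    payload["formulae"] = [f.value for f in config.formulae]
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source) -> CVConfig:
    path = Path(source)
    payload = yaml.safe_load(path.read_text() if path.exists() else source)
    payload["formulae"] = tuple(payload.get("formulae", ()))
    if "hyperparams" in payload and payload["hyperparams"] is None:
        payload.pop("hyperparams")
    return CVConfig(**{k: v for k, v in payload.items() if v is not None or k == "hyperparams"})


def _reports_frame(reports) -> pd.DataFrame:
    rows = []
    for rep in reports:
        d = rep.to_dict()
        d["groups"] = " vs ".join(map(str, d["groups"]))
        rows.append(d)
    return pd.DataFrame(rows)


def run_report(
    records: pd.DataFrame,
    metrics_frame: pd.DataFrame,
    test_reports,
    out_dir,
    config: Optional[CVConfig] = None,
    summary_text: str = "",
) -> dict:
    """Write the deterministic report bundle; returns {name: path}.

    ``test_reports`` is a flat iterable of :class:`iolens.stats.TestReport`
    (may be empty).  Strata with no eyes are simply absent from the metric
    tables; the plain-text summary notes which cells are present.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["records"] = out_dir / "prediction_records.csv"
    records.to_csv(paths["records"], index=False)

    paths["metrics_csv"] = out_dir / "metrics.csv"
    metrics_frame.to_csv(paths["metrics_csv"], index=False)
    paths["metrics_json"] = out_dir / "metrics.json"
    paths["metrics_json"].write_text(
        json.dumps(metrics_frame.to_dict(orient="records"), indent=2)
    )

    reports = list(test_reports)
    paths["tests_csv"] = out_dir / "test_reports.csv"
    _reports_frame(reports).to_csv(paths["tests_csv"], index=False)
    paths["tests_json"] = out_dir / "test_reports.json"
    paths["tests_json"].write_text(
        json.dumps([r.to_dict() for r in reports], indent=2, default=str)
    )

    if config is not None:
        paths["config"] = out_dir / "run_config.yaml"
        config_to_yaml(config, paths["config"])

    lines = [summary_text] if summary_text else []
    present = {
        (row["formula"], row["stratum"]) for _, row in metrics_frame.iterrows()
    }
    lines.append(f"metric cells present: {len(present)}")
    empty_note = metrics_frame.attrs.get("empty_strata")
    if empty_note:
        lines.append(f"empty strata (no eyes): {empty_note}")
    paths["summary"] = out_dir / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    return paths
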