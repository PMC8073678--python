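"""Batch pipeline: ingest -> detect -> featureize -> group statistics.

``run_pipeline`` consumes a directory of OpenFace-dialect CSVs (one per
subject) plus a ``metadata.csv`` (subject_id, group, sex, age_months, iq)
and writes the events table, features table, listwise-exclusion log, the
machine-readable statistics report (JSON), a human-readable summary and a
run manifest.  Identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ParameterError, PipelineError
from .features import DV_MANOVA

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters, each within its documented range."""

    confidence_threshold: float = 0.75
    smooth_width_frames: int = 4
    activation_tau: float = 0.5
    min_event_s: float = 1.0
    social_overlap_threshold: float = 0.5
    max_gap_s: float = 0.5
    alpha: float = 0.05
    m_tests: int = 7
    dv_set: tuple[str, ...] = DV_MANOVA
    seed: int = 0
    input_dir: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.dv_set = tuple(self.dv_set)
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ParameterError("confidence_threshold outside [0, 1]")
        if self.smooth_width_frames < 1:
            raise ParameterError("smooth_width_frames must be >= 1")
        if self.activation_tau < 0:
            raise ParameterError("activation_tau must be >= 0")
        if self.min_event_s < 0:
            raise ParameterError("min_event_s must be >= 0")
        if not 0.0 < self.social_overlap_threshold <= 1.0:
            raise ParameterError("social_overlap_threshold outside (0, 1]")
        if self.max_gap_s < 0:
            raise ParameterError("max_gap_s must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha outside (0, 1)")
        if self.m_tests < 1:
            raise ParameterError("m_tests must be >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dv_set"] = list(self.dv_set)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _json_default(obj):
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage; returns the artifact paths.

    Errors surface with the failing stage's name (and subject id where
    applicable).
    """
    from .events import events_to_records
    from .experiments import analyze_trace
    from .features import assemble_cohort, subject_features
    from .model import SmileGroupModel
    from .openface import read_openface_csv

    config.validate()
    if not config.input_dir or not config.output_dir:
        raise PipelineError("[config] input_dir and output_dir are required")
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # ingest ----------------------------------------------------------------
    meta_path = in_dir / "metadata.csv"
    if not meta_path.exists():
        raise PipelineError(f"[ingest] metadata.csv not found in {in_dir}")
    metadata = pd.read_csv(meta_path)
    subject_files = {
        p.stem: p for p in sorted(in_dir.glob("*.csv")) if p.name != "metadata.csv"
    }
    if not subject_files:
        raise PipelineError(f"[ingest] no subject CSV files in {in_dir}")

    event_rows = []
    vectors = []
    recall_info = []
    for row in metadata.itertuples(index=False):
        sid = str(row.subject_id)
        if sid not in subject_files:
            raise PipelineError(f"[ingest] subject {sid}: CSV file missing")
        try:
            series = read_openface_csv(subject_files[sid], sid)
        except Exception as exc:
            raise PipelineError(f"[ingest] subject {sid}: {exc}") from exc
        try:
            events, recording = analyze_trace(series, config)
        except Exception as exc:
            raise PipelineError(f"[detect] subject {sid}: {exc}") from exc
        event_rows.extend(events_to_records(events))
        if recording.usable_seconds <= 0:
            logger.warning("subject %s: no usable frames; excluded from features", sid)
            continue
        try:
            vectors.append(subject_features(events, recording.usable_seconds, {
                "subject_id": sid,
                "group": row.group,
                "sex": getattr(row, "sex", ""),
                "age_months": getattr(row, "age_months", float("nan")),
                "iq": getattr(row, "iq", float("nan")),
            }))
        except Exception as exc:
            raise PipelineError(f"[features] subject {sid}: {exc}") from exc
        recall_info.append(sid)

    # featureize ------------------------------------------------------------
    try:
        cohort = assemble_cohort(vectors, dv_names=config.dv_set)
    except Exception as exc:
        raise PipelineError(f"[features] cohort assembly: {exc}") from exc

    # stats -----------------------------------------------------------------
    try:
        results = SmileGroupModel(
            cohort, dvs=config.dv_set, alpha=config.alpha
        ).fit()
    except Exception as exc:
        raise PipelineError(f"[stats] {exc}") from exc

    # artifacts -------------------------------------------------------------
    artifacts: dict[str, Path] = {}
    events_df = pd.DataFrame(event_rows)
    artifacts["events"] = out_dir / "events.csv"
    events_df.to_csv(artifacts["events"], index=False)

    artifacts["features"] = out_dir / "features.csv"
    cohort.data.to_csv(artifacts["features"], index=False)

    artifacts["exclusions"] = out_dir / "exclusions.log"
    with open(artifacts["exclusions"], "w") as fh:
        for sid, missing in cohort.exclusions:
            fh.write(f"{sid}\tmissing: {','.join(missing)}\n")

    artifacts["stats"] = out_dir / "stats.json"
    with open(artifacts["stats"], "w") as fh:
        json.dump(results.to_dict(), fh, indent=1, sort_keys=True,
                  default=_json_default)

    artifacts["report"] = out_dir / "report.txt"
    artifacts["report"].write_text(results.summary() + "\n")

    import scipy
    artifacts["manifest"] = out_dir / "manifest.json"
    with open(artifacts["manifest"], "w") as fh:
        json.dump({
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "n_subjects_ingested": len(recall_info),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
            },
        }, fh, indent=1, sort_keys=True)
    return artifacts
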