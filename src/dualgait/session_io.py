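"""On-disk formats: JSON-Lines sessions, CSV feature tables, YAML config.

Sessions are stored one trial per line (streamable and append-friendly for a
continuously running kiosk), UTF-8, with a ``schema_version`` field; readers
accept only known versions and re-validate every invariant the writer
enforces (one shared validator).  Numeric fields round-trip at full
precision.  Feature tables are RFC-4180 CSV with a mandatory header of
``subject_id, trial_index``, the 12 canonical feature columns and ``mmse``.
"""

from __future__ import annotations

import json
import math
import os
from typing import Any, Sequence

import pandas as pd
import yaml

from .errors import SessionParseError, ValidationError
from .types import FEATURE_NAMES, FeatureVector, SubjectProfile, TrialSession

FEATURE_TABLE_COLUMNS = ("subject_id", "trial_index", *FEATURE_NAMES, "mmse")

FeatureRow = tuple[str, int, FeatureVector, int]


def write_sessions(sessions: Sequence[TrialSession],
                   path: str | os.PathLike) -> None:
    """Write sessions as JSON-Lines, one validated record per line."""
    if len(sessions) == 0:
        raise ValidationError("cannot write an empty session sequence")
    for session in sessions:
        session.validate()
    with open(path, "w", encoding="utf-8") as fh:
        for session in sessions:
            fh.write(json.dumps(session.to_dict(), ensure_ascii=False,
                                sort_keys=False))
            fh.write("\n")


def read_sessions(path: str | os.PathLike) -> list[TrialSession]:
    """Read a JSON-Lines session file, re-validating every record.

    Malformed lines raise :class:`SessionParseError` with the line number;
    records violating any invariant raise :class:`ValidationError` (or
    :class:`SchemaVersionError` for unknown schema versions).
    """
    sessions = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise SessionParseError(str(exc), line_number=lineno) from exc
            session = TrialSession.from_dict(record)
            session.validate()
            sessions.append(session)
    return sessions


def write_feature_table(features: Sequence[FeatureRow],
                        path: str | os.PathLike) -> None:
    """Write per-trial feature rows as CSV (header mandatory, '.' decimals)."""
    rows = []
    for subject_id, trial_index, fv, mmse in features:
        for name in FEATURE_NAMES:
            if not math.isfinite(getattr(fv, name)):
                raise ValidationError(f"non-finite feature {name} for "
                                      f"{subject_id}/{trial_index}", field=name)
        rows.append({"subject_id": subject_id, "trial_index": trial_index,
                     **fv.to_dict(), "mmse": mmse})
    df = pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
    df.to_csv(path, index=False, lineterminator="\n")


def read_feature_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature-table CSV, checking schema and finiteness."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing columns {missing}",
                              field=missing[0])
    values = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    if not (values == values).all() or not (abs(values) < float("inf")).all():
        raise ValidationError("feature table contains non-finite values")
    return df


def feature_table_from_pairs(pairs: Sequence[tuple[TrialSession, FeatureVector]]
                             ) -> pd.DataFrame:
    """Assemble an in-memory feature table from (session, features) pairs."""
    rows = [{"subject_id": s.subject_id, "trial_index": s.trial_index,
             **fv.to_dict(), "mmse": s.mmse} for s, fv in pairs]
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def write_subjects(subjects: Sequence[SubjectProfile],
                   path: str | os.PathLike) -> None:
    """Write subject profiles (demographics, MMSE, latents) as CSV."""
    df = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age, "gender": s.gender,
        "mmse": s.mmse, "knee_amplitude_rad": s.knee_amplitude_rad,
        "step_interval_s": s.step_interval_s, "step_jitter_s": s.step_jitter_s,
        "calc_accuracy": s.calc_accuracy, "calc_time_s": s.calc_time_s,
        "learning_gain_rad": s.learning_gain_rad,
    } for s in subjects])
    df.to_csv(path, index=False, lineterminator="\n")


def load_config(path: str | os.PathLike) -> dict[str, Any]:
    """Load a run configuration (YAML with sections ``simulate``,
    ``extract``, ``estimate``, ``analyze``; absent sections default to {})."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    return {section: raw.get(section, {}) or {}
            for section in ("simulate", "extract", "estimate", "analyze")}
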