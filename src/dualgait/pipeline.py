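"""End-to-end helpers chaining simulation, extraction and estimation."""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import IncompleteTrialError
from .gait_features import ExtractionParams, extract_features
from .session_io import FEATURE_TABLE_COLUMNS
from .synthetic_cohort import CohortConfig, iter_subject_sessions
from .types import SubjectProfile, TrialSession

log = logging.getLogger(__name__)


def extract_feature_table(sessions: Iterable[TrialSession],
                          params: ExtractionParams | None = None
                          ) -> pd.DataFrame:
    """Extract the 12 features from every session into one table.

    Trials with any missing feature are dropped (complete-case modelling)
    with a logged count.
    """
    params = params or ExtractionParams()
    rows = []
    dropped = 0
    for session in sessions:
        try:
            fv = extract_features(session, params)
        except IncompleteTrialError as exc:
            log.warning("dropping incomplete trial: %s", exc)
            dropped += 1
            continue
        rows.append({"subject_id": session.subject_id,
                     "trial_index": session.trial_index,
                     **fv.to_dict(), "mmse": session.mmse})
    if dropped:
        log.info("dropped %d incomplete trial(s)", dropped)
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))


def simulate_feature_table(config: CohortConfig, rng: np.random.Generator,
                           params: ExtractionParams | None = None
                           ) -> tuple[list[SubjectProfile], pd.DataFrame]:
    """Simulate a cohort and extract its feature table, one subject at a
    time (sessions are not retained, keeping memory flat)."""
    subjects: list[SubjectProfile] = []
    parts: list[pd.DataFrame] = []
    for subject, sessions in iter_subject_sessions(config, rng):
        subjects.append(subject)
        parts.append(extract_feature_table(sessions, params))
    return subjects, pd.concat(parts, ignore_index=True)
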