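"""Session-level quality control.

A session enters the analysis only if the recording lasts at least the
configured minimum (55 s by default — feature extraction from shorter data is
possible but the reset-rate estimate degrades at low frequencies) and the
mood questionnaire was answered.  Sessions recorded under medication are kept
and merely flagged, matching the study protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import AnalysisConfig, EEGSession

__all__ = ["ExclusionRecord", "filter_sessions", "exclusion_log_frame"]

REASON_SHORT = "short_recording"
REASON_NO_SCORE = "missing_score"
REASON_BOTH = "both"


@dataclass(frozen=True)
class ExclusionRecord:
    session_id: str
    duration_s: float
    has_score: bool
    reason: str


def filter_sessions(
    sessions: list[EEGSession], config: AnalysisConfig
) -> tuple[list[EEGSession], list[tuple[EEGSession, ExclusionRecord]]]:
    """Partition sessions into (included, excluded-with-reason).

    Exclusion reasons: ``short_recording`` (duration < ``min_duration``),
    ``missing_score`` (no DD score), or ``both``.  Included sessions are the
    original objects, unmodified.
    """
    included: list[EEGSession] = []
    excluded: list[tuple[EEGSession, ExclusionRecord]] = []
    for s in sessions:
        short = s.duration < config.min_duration
        unscored = s.dd_score is None
        if not short and not unscored:
            included.append(s)
            continue
        reason = REASON_BOTH if (short and unscored) else (
            REASON_SHORT if short else REASON_NO_SCORE
        )
        excluded.append(
            (s, ExclusionRecord(s.session_id, s.duration, not unscored, reason))
        )
    return included, excluded


def exclusion_log_frame(excluded):
    """Exclusion log as a DataFrame ready to write as TSV."""
    import pandas as pd

    return pd.DataFrame(
        [
            {"session_id": r.session_id, "duration_s": r.duration_s,
             "has_score": r.has_score, "reason": r.reason}
            for _, r in excluded
        ]
    )
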