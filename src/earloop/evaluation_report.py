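"""Descriptive session summaries: chill counts, inclusion checks, baselines.

Group inferential statistics are intentionally out of scope; the report
emits tidy tables any stats environment can consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError
from .session_io import SessionLog


@dataclass
class ConditionSummary:
    condition: str
    n_chills: int  # slots 2-7 only
    vas: dict[str, float]
    decoded_means: list[float | None]
    baseline_corrected: list[float | None]


@dataclass
class InclusionResult:
    included: bool
    reasons: list[str]
    self_chills: int
    other_chills: int
    self_vas_mean: float
    other_vas_mean: float


def count_chills(log: SessionLog, condition: str | None = None) -> int:
    """Total key presses over playlist slots 2-7 (the baseline is excluded).

    Presses outside their song's window are excluded with a warning.
    """
    records = [
        r for r in log.song_records if condition is None or r.condition == condition
    ]
    total = 0
    for slot, rec in enumerate(records, start=1):
        if slot == 1:
            continue
        for t in rec.chill_press_times:
            if rec.onset <= t <= rec.onset + rec.duration:
                total += 1
            else:
                warnings.warn(
                    f"chill press at {t} s outside song {rec.song_id}; excluded"
                )
    return total


def check_inclusion(calibration_log: SessionLog, min_chill_diff: int = 3) -> InclusionResult:
    """Included iff (self chills - other chills >= 3) and mean self VAS > other."""
    self_recs = [r for r in calibration_log.song_records if r.condition == "self"]
    other_recs = [r for r in calibration_log.song_records if r.condition == "other"]
    if not self_recs or not other_recs:
        raise ValidationError("calibration log must contain self and other songs")
    for r in self_recs + other_recs:
        if "pleasure" not in r.vas_ratings:
            raise ValidationError(f"song {r.song_id} is missing its pleasure rating")
    self_chills = sum(len(r.chill_press_times) for r in self_recs)
    other_chills = sum(len(r.chill_press_times) for r in other_recs)
    self_vas = float(np.mean([r.vas_ratings["pleasure"] for r in self_recs]))
    other_vas = float(np.mean([r.vas_ratings["pleasure"] for r in other_recs]))
    reasons = []
    if self_chills - other_chills < min_chill_diff:
        reasons.append("chill criterion")
    if not self_vas > other_vas:
        reasons.append("pleasure criterion")
    return InclusionResult(
        included=not reasons,
        reasons=reasons,
        self_chills=self_chills,
        other_chills=other_chills,
        self_vas_mean=self_vas,
        other_vas_mean=other_vas,
    )


def baseline_correct(decoded_means: list[float | None]) -> list[float | None]:
    """Subtract the slot-1 (baseline song) mean from every slot's mean."""
    if not decoded_means or decoded_means[0] is None:
        raise ParameterError("baseline (slot 1) decoded mean is missing")
    base = decoded_means[0]
    return [None if m is None else m - base for m in decoded_means]


def summarize_condition(
    condition: str,
    log: SessionLog,
    decoded_means: list[float | None],
    vas: dict[str, float] | None = None,
) -> ConditionSummary:
    return ConditionSummary(
        condition=condition,
        n_chills=count_chills(log, condition),
        vas=vas or {},
        decoded_means=decoded_means,
        baseline_corrected=baseline_correct(decoded_means),
    )


def summaries_to_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """One row per condition x slot, suitable for CSV export."""
    rows = []
    for s in summaries:
        for slot, (m, c) in enumerate(zip(s.decoded_means, s.baseline_corrected), start=1):
            rows.append(
                {
                    "condition": s.condition,
                    "slot": slot,
                    "decoded_mean": m,
                    "baseline_corrected": c,
                    "n_chills_slots_2_7": s.n_chills,
                }
            )
    return pd.DataFrame(rows)
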