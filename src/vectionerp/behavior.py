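"""Vection behavior metrics and left- vs. right-hander group comparisons.

Per trial, button-press streams yield vection presence, onset latency (first
vection onset minus motion onset), and duration (total vection time across
intervals; an interval still open at trial end closes there).  Per
participant and condition, presence is a count over all trials while latency
and duration are medians over vection-present trials only; strength is the
median rating over all trials (absent trials rate 0).  Groups are compared
per measure and condition with the Wilcoxon rank-sum test (normal
approximation with average ranks, tie-corrected variance and continuity
correction), Bonferroni-corrected over the configured family (default 8 = 4
measures x 2 conditions), with effect size r = Z / sqrt(N).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Condition, Direction, EventKind, TrialBehavior, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "VectionSummary",
    "GroupComparison",
    "derive_trial_metrics",
    "summarize_participant",
    "compare_groups",
    "MEASURES",
]

MEASURES = ("presence_count", "onset_latency_s", "duration_s", "strength")


def derive_trial_metrics(
    trial: int,
    condition: Condition | str,
    direction: Direction | str,
    motion_onset_s: float,
    motion_offset_s: float,
    events: list[tuple[float, EventKind]],
    strength: int,
    trial_end_s: float | None = None,
) -> TrialBehavior:
    """Build a :class:`TrialBehavior` from time-ordered button events.

    ``events`` are (time s, kind) pairs; vection onset/offset kinds alternate
    per direction button.  An onset still open at trial end is closed at
    trial end (logged); an offset without a preceding onset is dropped with a
    warning.
    """
    if trial_end_s is None:
        trial_end_s = motion_offset_s + 10.0
    intervals: list[tuple[float, float]] = []
    open_onset: float | None = None
    last_t = -math.inf
    for t, kind in events:
        if t < last_t:
            raise ValidationError("events must be time-ordered")
        last_t = t
        if kind in (EventKind.VECTION_ONSET_CW, EventKind.VECTION_ONSET_CCW):
            if open_onset is None:
                open_onset = t
        elif kind in (EventKind.VECTION_OFFSET_CW, EventKind.VECTION_OFFSET_CCW):
            if open_onset is None:
                logger.warning("trial %d: vection offset before any onset; dropped", trial)
                continue
            intervals.append((open_onset, t))
            open_onset = None
    if open_onset is not None:
        logger.info("trial %d: open vection interval closed at trial end", trial)
        intervals.append((open_onset, trial_end_s))
    return TrialBehavior(
        trial=trial,
        condition=Condition(condition),
        direction=Direction(direction),
        motion_onset_time=motion_onset_s,
        motion_offset_time=motion_offset_s,
        vection_intervals=intervals,
        strength=strength,
    )


@dataclass
class VectionSummary:
    """Per-participant, per-condition behavioral summary (Table-style medians)."""

    subject: str
    condition: Condition
    n_trials: int
    presence_count: int
    onset_latency_s: float  # median over vection-present trials; NaN if none
    duration_s: float  # median total vection time over vection-present trials
    strength: float  # median rating over all trials

    def as_dict(self) -> dict:
        return {
            "subject": self.subject,
            "condition": self.condition.value,
            "n_trials": self.n_trials,
            "presence_count": self.presence_count,
            "onset_latency_s": self.onset_latency_s,
            "duration_s": self.duration_s,
            "strength": self.strength,
        }


def trial_presence(t: TrialBehavior) -> bool:
    return len(t.vection_intervals) > 0


def trial_latency(t: TrialBehavior) -> float:
    return t.vection_intervals[0][0] - t.motion_onset_time


def trial_duration(t: TrialBehavior) -> float:
    return sum(b - a for a, b in t.vection_intervals)


def summarize_participant(
    trials: list[TrialBehavior], condition: Condition | str, subject: str = ""
) -> VectionSummary:
    """Summarize one participant's trials of one condition."""
    cond = Condition(condition)
    sel = [t for t in trials if t.condition == cond]
    if not sel:
        raise ValidationError(f"no trials for condition {cond.value}")
    present = [t for t in sel if trial_presence(t)]
    if present:
        latency = float(np.median([trial_latency(t) for t in present]))
        duration = float(np.median([trial_duration(t) for t in present]))
    else:
        latency = duration = float("nan")
    return VectionSummary(
        subject=subject,
        condition=cond,
        n_trials=len(sel),
        presence_count=len(present),
        onset_latency_s=latency,
        duration_s=duration,
        strength=float(np.median([t.strength for t in sel])),
    )


# ---------------------------------------------------------------------------
# Group comparison


@dataclass
class GroupComparison:
    measure: str
    condition: str
    z: float
    p: float
    p_adjusted: float
    r: float
    n: tuple[int, int]
    median_left: float
    iqr_left: float
    median_right: float
    iqr_right: float

    def as_dict(self) -> dict:
        return {
            "measure": self.measure,
            "condition": self.condition,
            "Z": self.z,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "r": self.r,
            "n_left": self.n[0],
            "n_right": self.n[1],
            "median_left": self.median_left,
            "iqr_left": self.iqr_left,
            "median_right": self.median_right,
            "iqr_right": self.iqr_right,
        }


def ranksum_z(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum Z (left vs. right) and two-sided normal-approximation p.

    Average ranks for ties, tie-corrected variance, continuity correction.
    Sign convention: positive Z means the left-hander group ranks higher.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    n1, n2 = len(left), len(right)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 observations")
    pooled = np.concatenate([left, right])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1))
    var = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
    if var <= 0:
        return 0.0, 1.0
    d = w - mu
    d_corr = d - 0.5 * np.sign(d) if d != 0 else 0.0
    z = d_corr / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def compare_groups(
    left_values,
    right_values,
    measure: str = "",
    condition: str = "",
    bonferroni_m: int = 8,
) -> GroupComparison:
    """Rank-sum comparison of per-participant summaries, left vs. right handers.

    Missing values (participants with no vection-present trials for latency or
    duration) are excluded.  r = Z / sqrt(total observations entering the test).
    """
    left = np.asarray([v for v in np.asarray(left_values, dtype=float) if not np.isnan(v)])
    right = np.asarray([v for v in np.asarray(right_values, dtype=float) if not np.isnan(v)])
    z, p = ranksum_z(left, right)
    n = len(left) + len(right)
    r = z / math.sqrt(n)

    def iqr(x):
        return float(np.percentile(x, 75) - np.percentile(x, 25)) if len(x) else float("nan")

    return GroupComparison(
        measure=measure,
        condition=condition,
        z=z,
        p=p,
        p_adjusted=min(1.0, bonferroni_m * p),
        r=r,
        n=(len(left), len(right)),
        median_left=float(np.median(left)),
        iqr_left=iqr(left),
        median_right=float(np.median(right)),
        iqr_right=iqr(right),
    )


def behavior_comparison_table(
    summaries: list[VectionSummary],
    groups: dict[str, str],
    bonferroni_m: int = 8,
) -> pd.DataFrame:
    """All 4 measures x 2 conditions group comparisons as a results table."""
    df = pd.DataFrame([s.as_dict() for s in summaries])
    rows = []
    for cond in (Condition.COHERENT.value, Condition.INCOHERENT.value):
        sub = df[df["condition"] == cond]
        for measure in MEASURES:
            lv = sub[sub["subject"].map(groups) == "left"][measure].to_numpy()
            rv = sub[sub["subject"].map(groups) == "right"][measure].to_numpy()
            rows.append(
                compare_groups(lv, rv, measure=measure, condition=cond,
                               bonferroni_m=bonferroni_m).as_dict()
            )
    return pd.DataFrame(rows)
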