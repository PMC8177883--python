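"""Behavioural measures derived from event logs.

Each block's timeline is partitioned into labelled periods:

* ``ITI`` — cue-free time inside the trading window (the baseline),
* ``CS_pending`` — the delay between a cue trigger and its onset (the cue is
  not yet visible, so this time counts toward neither baseline nor cue rates),
* ``CS_unshielded`` / ``CS_shielded`` — visible cue time before/after a
  shield activation, labelled by cue type,
* ``post_trading_tail`` — time after the trading window closes while pending
  cues and countdowns resolve (excluded from every rate denominator).

Rates are time-weighted (clicks per minute of period time).  The preference
ratio is the share of baseline clicks on the punished planet: R1 ITI rate /
(R1 + R2 ITI rate), 0.5 meaning no preference.  Conditioned suppression per
cue type aggregates unshielded cue time across the punishment phase and is
reported as CS rate / (CS rate + ITI rate), so 0.5 means clicking is
unchanged during the cue, 0 means complete suppression, and values above 0.5
mean facilitation; the raw quotient CS/ITI is available as the ``literal``
formula.  Shield use is the percentage of offered shields that were
activated, per cue type.  Missing values (no unshielded exposure, no offered
shield, no baseline clicks) stay missing — nothing is imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EventLog, validate_event_log

PERIOD_COLUMNS = ["block", "phase", "label", "cs_type", "start_s", "end_s", "duration_s"]


def segment_periods(log: EventLog, block_duration_s: float = 180.0,
                    validate: bool = True) -> pd.DataFrame:
    """Partition each block's timeline into labelled intervals.

    The returned intervals are half-open ``[start, end)``, non-overlapping,
    and sum exactly to each block's total logged timeline.
    """
    if validate:
        violations = validate_event_log(log)
        if violations:
            raise ValueError("invalid event log: " + "; ".join(violations[:3]))
    rows = []
    for block in log.blocks():
        events = log.block_events(block)
        phase = events[0].phase
        block_end = max(events[-1].time_s, block_duration_s)
        trading_end = min(block_duration_s, block_end)

        # Cue episodes: (trigger_t, onset_t, activation_t or None, offset_t, type)
        episodes = []
        current = None
        for e in events:
            if e.kind == "cs_trigger":
                current = {"trigger": e.time_s, "cs_type": e.cs_type, "onset": None,
                           "activated": None, "offset": None}
            elif e.kind == "cs_onset" and current is not None:
                current["onset"] = e.time_s
            elif e.kind == "shield_activated" and current is not None:
                current["activated"] = e.time_s
            elif e.kind == "cs_offset" and current is not None:
                current["offset"] = e.time_s
                episodes.append(current)
                current = None

        def add(label, cs_type, start, end):
            start, end = min(start, trading_end), min(end, trading_end)
            if end > start:
                rows.append((block, phase, label, cs_type, start, end, end - start))

        cursor = 0.0
        for ep in episodes:
            add("ITI", "none", cursor, ep["trigger"])
            add("CS_pending", ep["cs_type"], ep["trigger"], ep["onset"])
            act = ep["activated"]
            if act is None:
                add("CS_unshielded", ep["cs_type"], ep["onset"], ep["offset"])
            else:
                add("CS_unshielded", ep["cs_type"], ep["onset"], act)
                add("CS_shielded", ep["cs_type"], act, ep["offset"])
            cursor = ep["offset"]
        add("ITI", "none", cursor, trading_end)
        if block_end > trading_end:
            rows.append((block, phase, "post_trading_tail", "none",
                         trading_end, block_end, block_end - trading_end))
    return pd.DataFrame(rows, columns=PERIOD_COLUMNS)


def _clicks_in_periods(log: EventLog, periods: pd.DataFrame) -> pd.DataFrame:
    """Count clicks per (block, label, cs_type, planet) using period boundaries.

    Intervals are attributed as ``(start, end]``: a cue-triggering click sits
    exactly on the ITI/pending boundary and belongs to the baseline — the cue
    it caused is not yet visible when the click happens.  Clicks at the very
    start of a block (t = 0) count toward the first interval.
    """
    counts = []
    for block in log.blocks():
        block_periods = periods[periods["block"] == block]
        clicks = [(e.time_s, e.planet) for e in log.block_events(block) if e.kind == "click"]
        for p in block_periods.itertuples(index=False):
            n = {"R1": 0, "R2": 0}
            for t, planet in clicks:
                if (p.start_s < t <= p.end_s) or (t == p.start_s == 0.0):
                    n[planet] += 1
            counts.append((block, p.phase, p.label, p.cs_type, p.duration_s,
                           n["R1"], n["R2"]))
    return pd.DataFrame(counts, columns=["block", "phase", "label", "cs_type",
                                         "duration_s", "clicks_R1", "clicks_R2"])


def iti_rates(log: EventLog, block: int, block_duration_s: float = 180.0) -> dict:
    """Baseline (cue-free) click rates for one block, in clicks/min."""
    periods = segment_periods(log, block_duration_s)
    counts = _clicks_in_periods(log, periods)
    iti = counts[(counts["block"] == block) & (counts["label"] == "ITI")]
    minutes = iti["duration_s"].sum() / 60.0
    if minutes <= 0:
        return {"iti_rate_R1": math.nan, "iti_rate_R2": math.nan,
                "overall_iti_rate": math.nan, "iti_minutes": 0.0}
    r1 = iti["clicks_R1"].sum() / minutes
    r2 = iti["clicks_R2"].sum() / minutes
    return {"iti_rate_R1": r1, "iti_rate_R2": r2,
            "overall_iti_rate": r1 + r2, "iti_minutes": minutes}


def preference_ratio(log: EventLog, block: int, block_duration_s: float = 180.0) -> float:
    """Share of baseline clicks on the punished planet; NaN if no baseline clicks."""
    r = iti_rates(log, block, block_duration_s)
    total = r["iti_rate_R1"] + r["iti_rate_R2"]
    if not total > 0:
        return math.nan
    return r["iti_rate_R1"] / total


def suppression_ratios(log: EventLog, block_duration_s: float = 180.0,
                       formula: str = "standard") -> dict:
    """Conditioned-suppression ratio per cue type, aggregated across the
    punishment phase.  NaN for a cue type with no unshielded exposure."""
    if formula not in ("standard", "literal"):
        raise ValueError("formula must be 'standard' or 'literal'")
    periods = segment_periods(log, block_duration_s)
    counts = _clicks_in_periods(log, periods)
    punish = counts[counts["phase"] == "punish"]
    iti = punish[punish["label"] == "ITI"]
    iti_minutes = iti["duration_s"].sum() / 60.0
    iti_rate = ((iti["clicks_R1"].sum() + iti["clicks_R2"].sum()) / iti_minutes
                if iti_minutes > 0 else math.nan)
    out = {}
    for cs, tag in (("CS+", "CSplus"), ("CS-", "CSminus")):
        cue = punish[(punish["label"] == "CS_unshielded") & (punish["cs_type"] == cs)]
        minutes = cue["duration_s"].sum() / 60.0
        if minutes <= 0 or not np.isfinite(iti_rate):
            out[f"suppression_{tag}"] = math.nan
            continue
        cs_rate = (cue["clicks_R1"].sum() + cue["clicks_R2"].sum()) / minutes
        if formula == "standard":
            denom = cs_rate + iti_rate
            out[f"suppression_{tag}"] = cs_rate / denom if denom > 0 else math.nan
        else:
            out[f"suppression_{tag}"] = cs_rate / iti_rate if iti_rate > 0 else math.nan
    return out


def shield_use(log: EventLog) -> dict:
    """Percentage of offered shields activated, per cue type; NaN if none offered."""
    offered = {"CS+": 0, "CS-": 0}
    used = {"CS+": 0, "CS-": 0}
    for e in log:
        if e.kind == "shield_offered":
            offered[e.cs_type] += 1
        elif e.kind == "shield_activated":
            used[e.cs_type] += 1
    out = {}
    for cs, tag in (("CS+", "CSplus"), ("CS-", "CSminus")):
        out[f"shield_use_{tag}"] = (100.0 * used[cs] / offered[cs]
                                    if offered[cs] > 0 else math.nan)
    return out


def points_per_block(log: EventLog) -> dict[int, int]:
    """Net point change within each block."""
    out = {}
    for block in log.blocks():
        out[block] = sum(e.points_delta for e in log.block_events(block))
    return out


def summarise_blocks(log: EventLog, block_duration_s: float = 180.0) -> pd.DataFrame:
    """Per-block instrumental metrics for one participant."""
    points = points_per_block(log)
    rows = []
    for block in log.blocks():
        phase = log.block_events(block)[0].phase
        r = iti_rates(log, block, block_duration_s)
        total = r["iti_rate_R1"] + r["iti_rate_R2"]
        ratio = r["iti_rate_R1"] / total if total > 0 else math.nan
        rows.append({"participant_id": log.participant_id, "block": block,
                     "phase": phase, **{k: r[k] for k in
                                        ("iti_rate_R1", "iti_rate_R2", "overall_iti_rate")},
                     "preference_ratio": ratio, "points_gained": points[block]})
    return pd.DataFrame(rows)


def summarise_pavlovian(log: EventLog, block_duration_s: float = 180.0,
                        suppression_formula: str = "standard") -> dict:
    """Punishment-phase-aggregate Pavlovian metrics for one participant."""
    return {"participant_id": log.participant_id,
            **suppression_ratios(log, block_duration_s, suppression_formula),
            **shield_use(log)}


def collapse_pre(block_summary: pd.DataFrame) -> pd.DataFrame:
    """Average the pre-punishment blocks of each participant into one 'Pre' row.

    Punishment blocks are renumbered 1..k.  The returned ``block`` column is
    a string label ('Pre', '1', '2', ...).
    """
    metric_cols = [c for c in block_summary.columns
                   if c not in ("participant_id", "block", "phase")]
    out = []
    for pid, df in block_summary.groupby("participant_id", sort=True):
        pre = df[df["phase"] == "pre"]
        if len(pre):
            row = {"participant_id": pid, "block": "Pre", "phase": "pre"}
            row.update({c: pre[c].mean() for c in metric_cols})
            out.append(row)
        punish = df[df["phase"] == "punish"].sort_values("block")
        for i, (_, r) in enumerate(punish.iterrows(), start=1):
            row = {"participant_id": pid, "block": str(i), "phase": "punish"}
            row.update({c: r[c] for c in metric_cols})
            out.append(row)
    return pd.DataFrame(out, columns=["participant_id", "block", "phase"] + metric_cols)


# ---- exclusions --------------------------------------------------------

RT_MIN_S = 1.0
RT_MAX_S = 30.0


@dataclass
class ExclusionResult:
    retained_ids: list[str]
    excluded: pd.DataFrame    # participant_id, reason


def apply_exclusions(self_reports: pd.DataFrame,
                     questionnaires: pd.DataFrame) -> ExclusionResult:
    """Engagement screen: retain a participant only if every check screen's
    mean response time is within [1, 30] s and both catch questions are
    correct.  Participants with missing fields are excluded as 'incomplete'.
    """
    rt_cols = [c for c in self_reports.columns if c.startswith("rt_")]
    quest = questionnaires.set_index("participant_id")
    retained, excluded = [], []
    for pid, df in self_reports.groupby("participant_id", sort=True):
        if pid not in quest.index:
            excluded.append((pid, "incomplete: no questionnaire record"))
            continue
        qrow = quest.loc[pid]
        if pd.isna(qrow.get("catch1_correct")) or pd.isna(qrow.get("catch2_correct")):
            excluded.append((pid, "incomplete: missing catch answers"))
            continue
        rts = df[rt_cols].to_numpy(dtype=float)
        rts = rts[~np.isnan(rts)]
        if rts.size == 0:
            excluded.append((pid, "incomplete: missing response times"))
            continue
        if rts.min() < RT_MIN_S or rts.max() > RT_MAX_S:
            excluded.append((pid, f"check-screen response time outside "
                                  f"[{RT_MIN_S:g}, {RT_MAX_S:g}] s"))
            continue
        if not (bool(qrow["catch1_correct"]) and bool(qrow["catch2_correct"])):
            excluded.append((pid, "failed a catch question"))
            continue
        retained.append(pid)
    # participants with questionnaires but no self-reports are incomplete too
    for pid in quest.index:
        if pid not in set(retained) | {e[0] for e in excluded}:
            excluded.append((pid, "incomplete: no self-report record"))
    excluded_df = pd.DataFrame(excluded, columns=["participant_id", "reason"])
    return ExclusionResult(retained_ids=retained, excluded=excluded_df)
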