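"""Canonical event-log container for simulated (or imported) task sessions.

Every session is an ordered list of timestamped events.  Times are seconds
from the start of the enclosing block; ``points_total`` is the running point
total across the whole session (attacks remove a fraction of it, so it must
carry across blocks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

EVENT_KINDS = (
    "click", "trade_start", "reward", "no_reward",
    "cs_trigger", "cs_onset", "cs_offset",
    "shield_offered", "shield_unavailable", "shield_activated",
    "attack", "block_end",
)

EVENT_COLUMNS = [
    "participant_id", "block", "phase", "time_s", "kind",
    "planet", "cs_type", "points_delta", "points_total",
]


@dataclass
class Event:
    time_s: float
    block_index: int          # 1-based
    phase: str                # "pre" | "punish"
    kind: str
    planet: str = "none"      # "R1" | "R2" | "none"
    cs_type: str = "none"     # "CS+" | "CS-" | "none"
    points_delta: int = 0
    points_total: int = 0


@dataclass
class EventLog:
    participant_id: str
    events: list[Event] = field(default_factory=list)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def append(self, event: Event) -> None:
        self.events.append(event)

    def blocks(self) -> list[int]:
        return sorted({e.block_index for e in self.events})

    def block_events(self, block_index: int) -> list[Event]:
        return [e for e in self.events if e.block_index == block_index]

    def final_points(self) -> int:
        return self.events[-1].points_total if self.events else 0

    # ---- serialisation -------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (self.participant_id, e.block_index, e.phase, e.time_s, e.kind,
             e.planet, e.cs_type, e.points_delta, e.points_total)
            for e in self.events
        ]
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, participant_id: str | None = None) -> "EventLog":
        if participant_id is None:
            ids = df["participant_id"].unique()
            if len(ids) != 1:
                raise ValueError("dataframe holds multiple participants; pass participant_id")
            participant_id = str(ids[0])
        else:
            df = df[df["participant_id"] == participant_id]
        events = [
            Event(time_s=float(r.time_s), block_index=int(r.block), phase=str(r.phase),
                  kind=str(r.kind), planet=str(r.planet), cs_type=str(r.cs_type),
                  points_delta=int(r.points_delta), points_total=int(r.points_total))
            for r in df.itertuples(index=False)
        ]
        return cls(participant_id=str(participant_id), events=events)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for e in self.events:
                rec = {"participant_id": self.participant_id, **asdict(e)}
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "EventLog":
        events, pid = [], None
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                pid = rec.pop("participant_id")
                events.append(Event(**rec))
        if pid is None:
            raise ValueError(f"empty event log file: {path}")
        return cls(participant_id=pid, events=events)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def logs_to_dataframe(logs: Iterable[EventLog]) -> pd.DataFrame:
    frames = [log.to_dataframe() for log in logs]
    if not frames:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def validate_event_log(log: EventLog) -> list[str]:
    """Check structural invariants; returns a list of human-readable violations.

    An empty list means the log is internally consistent: nondecreasing times
    within each block, balanced and non-overlapping cue episodes, shield
    activations only inside an offered window, and a running point total that
    matches the cumulative sum of point deltas.
    """
    violations: list[str] = []
    running = 0
    for block in log.blocks():
        events = log.block_events(block)
        last_t = float("-inf")
        cs_open = False          # between cs_onset and cs_offset
        cs_pending = False       # between cs_trigger and cs_onset
        shield_window = False    # between shield_offered and cs_offset
        shield_active = False
        for e in events:
            if e.kind not in EVENT_KINDS:
                violations.append(f"block {block}: unknown event kind {e.kind!r} at t={e.time_s}")
            if e.time_s < last_t:
                violations.append(
                    f"block {block}: time decreases at t={e.time_s} ({e.kind}) after {last_t}")
            last_t = e.time_s
            if e.kind == "cs_trigger":
                if cs_open or cs_pending:
                    violations.append(
                        f"block {block}: cs_trigger at t={e.time_s} while another CS is "
                        "pending or active (only one CS may run at a time)")
                cs_pending = True
            elif e.kind == "cs_onset":
                if cs_open:
                    violations.append(
                        f"block {block}: overlapping cs_onset at t={e.time_s} "
                        "(only one CS may run at a time)")
                cs_open, cs_pending = True, False
            elif e.kind == "cs_offset":
                if not cs_open:
                    violations.append(f"block {block}: cs_offset without matching cs_onset "
                                      f"at t={e.time_s}")
                cs_open = shield_window = shield_active = False
            elif e.kind == "shield_offered":
                shield_window = True
            elif e.kind == "shield_activated":
                if not shield_window:
                    violations.append(f"block {block}: shield_activated outside an offered "
                                      f"window at t={e.time_s}")
                if shield_active:
                    violations.append(f"block {block}: duplicate shield activation at t={e.time_s}")
                shield_active = True
            elif e.kind == "attack":
                if not cs_open:
                    violations.append(f"block {block}: attack outside a CS at t={e.time_s}")
                if shield_active:
                    violations.append(f"block {block}: attack despite active shield at t={e.time_s}")
                if e.cs_type != "CS+":
                    violations.append(f"block {block}: attack on {e.cs_type} at t={e.time_s} "
                                      "(only CS+ may attack)")
            running += e.points_delta
            if e.points_total != running:
                violations.append(
                    f"block {block}: points_total {e.points_total} != cumulative deltas "
                    f"{running} at t={e.time_s} ({e.kind})")
                running = e.points_total  # resynchronise to avoid cascading reports
        if cs_open or cs_pending:
            violations.append(f"block {block}: CS episode left unresolved at block end")
    return violations
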