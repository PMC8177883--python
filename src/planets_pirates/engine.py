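"""Event-driven simulator for the planets-and-pirates task.

The engine resolves participant actions (planet clicks, shield presses) into
trades, rewards, cue episodes and attacks, under the contingency schedule in
:class:`~planets_pirates.config.TaskConfig`.  A session is a sequence of
pre-punishment blocks followed by punishment blocks; trading is suspended at
``block_duration_s`` but any pending countdowns and cue episodes resolve to
completion before the block ends.

Scheduling rules
----------------
* A click always logs a ``click`` event.  If the clicked planet has no trade
  countdown running and no shield is active, it also starts a trade
  (``trade_start``) whose reward/no-reward outcome lands ``trade_countdown_s``
  later.  The two planets' countdowns are independent.
* In the punishment phase an additional cue roll is made for a click only
  when no cue is pending or active; a successful roll logs ``cs_trigger``
  immediately and the cue becomes visible (``cs_onset``) after ``cs_delay_s``.
  Cue rolls blocked by an ongoing cue are dropped, not queued.
* At cue onset, shield availability is drawn once; ``shield_offered`` or
  ``shield_unavailable`` is logged ``shield_charge_s`` after onset.  An
  unshielded CS+ ends in an ``attack`` removing ``attack_fraction`` of the
  current (non-negative) point total, rounded to the nearest point; CS- ends
  silently.  ``cs_offset`` is logged at onset + ``cs_duration_s`` either way.
* Activating an offered shield costs ``shield_cost_points``, cancels the
  attack, and blocks new trades until the cue ends.

Policies drive the participant side.  A policy proposes its next timed action
whenever asked and is shown every batch of events the engine emits, so
reactive policies (e.g. learning agents) can replan when the world changes.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from itertools import count
from typing import Protocol, runtime_checkable

import numpy as np

from .config import TaskConfig, PLANETS
from .events import Event, EventLog

ACTION_CLICK = "click"
ACTION_SHIELD = "shield"
ACTION_WAIT = "wait"


@dataclass
class Observation:
    """Snapshot of everything a participant can see."""

    time_s: float
    block_index: int
    phase: str
    trading_open: bool
    countdown: dict          # planet -> bool (trade countdown running)
    cs_type: str | None      # visible cue, None if none on screen
    cs_onset_s: float | None
    shield_offered: bool
    shield_active: bool
    points: int


@runtime_checkable
class Policy(Protocol):
    def begin_block(self, block_index: int, phase: str) -> None: ...

    def next_action(self, obs: Observation) -> tuple[float, str, str | None] | None:
        """Return (time_s, action_kind, planet-or-None), or None when done."""

    def observe(self, events: list[Event]) -> None: ...


class BasePolicy:
    """No-op policy scaffold; subclasses override what they need."""

    def begin_block(self, block_index: int, phase: str) -> None:
        pass

    def next_action(self, obs: Observation):
        return None

    def observe(self, events: list[Event]) -> None:
        pass


class NullPolicy(BasePolicy):
    """A participant who never acts."""


class ScriptedClicker(BasePolicy):
    """Clicks at a fixed metronomic interval, cycling through ``planets``.

    Useful for calibration runs: it ignores cues and shields entirely.
    """

    def __init__(self, interval_s: float, planets: tuple[str, ...] = ("R1", "R2"),
                 start_s: float | None = None):
        if interval_s <= 0:
            raise ValueError("interval_s must be > 0")
        self.interval_s = interval_s
        self.planets = tuple(planets)
        self.start_s = interval_s if start_s is None else start_s
        self._next_t = self.start_s
        self._i = 0

    def begin_block(self, block_index: int, phase: str) -> None:
        self._next_t = self.start_s
        self._i = 0

    def next_action(self, obs: Observation):
        if not obs.trading_open:
            return None
        return (self._next_t, ACTION_CLICK, self.planets[self._i % len(self.planets)])

    def observe(self, events: list[Event]) -> None:
        for e in events:
            if e.kind == "click":
                self._next_t = e.time_s + self.interval_s
                self._i += 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class TaskEngine:
    """Low-level, single-session simulation state machine.

    The engine exposes the primitive operations (``resolve_click``,
    ``activate_shield``, scheduled-event processing) so that tests and custom
    drivers can hand-trace the contingency rules; :func:`simulate_session`
    wires a policy to it.
    """

    def __init__(self, config: TaskConfig, seed: int = 0, participant_id: str = "p0"):
        self.config = config
        self.participant_id = participant_id
        self._seed = int(seed)
        self.log = EventLog(participant_id=participant_id)
        self.points = 0
        self.block_index = 0
        self.phase = "pre"
        self.clock = 0.0
        self._schedule: list[tuple[float, int, str, dict]] = []
        self._seq = count()
        self._countdown_until = {p: None for p in PLANETS}
        self._cs: dict | None = None

    # ---- block lifecycle ----------------------------------------------

    def start_block(self, block_index: int, phase: str) -> None:
        if phase not in ("pre", "punish"):
            raise ValueError(f"unknown phase {phase!r}")
        self.block_index = block_index
        self.phase = phase
        self.clock = 0.0
        self._schedule.clear()
        self._countdown_until = {p: None for p in PLANETS}
        self._cs = None
        ss = np.random.SeedSequence([self._seed, block_index])
        self._rng_reward, self._rng_cs, self._rng_shield = (
            np.random.default_rng(s) for s in ss.spawn(3))

    @property
    def trading_open(self) -> bool:
        return self.clock < self.config.block_duration_s

    def observation(self) -> Observation:
        cs_visible = self._cs is not None and self._cs["visible"]
        return Observation(
            time_s=self.clock,
            block_index=self.block_index,
            phase=self.phase,
            trading_open=self.trading_open,
            countdown={p: self._countdown_until[p] is not None for p in PLANETS},
            cs_type=self._cs["type"] if cs_visible else None,
            cs_onset_s=self._cs["onset_t"] if cs_visible else None,
            shield_offered=bool(cs_visible and self._cs["offered"]),
            shield_active=bool(cs_visible and self._cs["shield_active"]),
            points=self.points,
        )

    # ---- primitives ----------------------------------------------------

    def _emit(self, kind: str, planet: str = "none", cs_type: str = "none",
              points_delta: int = 0) -> Event:
        self.points += points_delta
        ev = Event(time_s=self.clock, block_index=self.block_index, phase=self.phase,
                   kind=kind, planet=planet, cs_type=cs_type,
                   points_delta=points_delta, points_total=self.points)
        self.log.append(ev)
        return ev

    def _push(self, time_s: float, tag: str, payload: dict) -> None:
        heapq.heappush(self._schedule, (time_s, next(self._seq), tag, payload))

    def next_scheduled_time(self) -> float | None:
        return self._schedule[0][0] if self._schedule else None

    def resolve_click(self, planet: str, time_s: float) -> list[Event]:
        """Log a click and apply trade/cue scheduling rules at ``time_s``."""
        if planet not in PLANETS:
            raise ValueError(f"unknown planet id {planet!r}")
        if time_s < self.clock:
            raise ValueError(
                f"click at t={time_s} precedes current log time t={self.clock}")
        self.clock = time_s
        batch = [self._emit("click", planet=planet)]
        if not self.trading_open:
            return batch  # tail click: recorded, but trading is suspended
        shield_active = self._cs is not None and self._cs["shield_active"]
        if self._countdown_until[planet] is None and not shield_active:
            batch.append(self._emit("trade_start", planet=planet))
            outcome_t = time_s + self.config.trade_countdown_s
            self._countdown_until[planet] = outcome_t
            success = bool(self._rng_reward.random() < self.config.reward_prob)
            self._push(outcome_t, "trade_outcome", {"planet": planet, "success": success})
        if self.phase == "punish" and self._cs is None:
            if self._rng_cs.random() < self.config.cs_prob:
                cs_type = self.config.cs_type_for(planet)
                batch.append(self._emit("cs_trigger", planet=planet, cs_type=cs_type))
                onset_t = time_s + self.config.cs_delay_s
                self._cs = {"type": cs_type, "trigger_t": time_s, "onset_t": onset_t,
                            "visible": False, "available": False, "offered": False,
                            "shield_active": False}
                self._push(onset_t, "cs_onset", {})
        return batch

    def activate_shield(self, time_s: float) -> list[Event]:
        """Press the shield button; valid only while a shield is on offer."""
        if time_s < self.clock:
            raise ValueError(f"shield press at t={time_s} precedes log time t={self.clock}")
        cs = self._cs
        if cs is None or not cs["visible"]:
            raise ValueError("shield activation with no CS on screen")
        if not cs["offered"]:
            raise ValueError("shield activation but no shield was offered for this CS")
        if cs["shield_active"]:
            raise ValueError("shield already active for this CS")
        if time_s >= cs["onset_t"] + self.config.cs_duration_s:
            raise ValueError("shield activation after the CS ended")
        self.clock = time_s
        cs["shield_active"] = True
        return [self._emit("shield_activated", cs_type=cs["type"],
                           points_delta=-self.config.shield_cost_points)]

    def process_next_scheduled(self) -> list[Event]:
        """Advance the clock to the earliest scheduled engine event and run it."""
        time_s, _, tag, payload = heapq.heappop(self._schedule)
        self.clock = time_s
        if tag == "trade_outcome":
            planet = payload["planet"]
            self._countdown_until[planet] = None
            if payload["success"]:
                return [self._emit("reward", planet=planet,
                                   points_delta=self.config.reward_points)]
            return [self._emit("no_reward", planet=planet)]
        if tag == "cs_onset":
            cs = self._cs
            cs["visible"] = True
            cs["available"] = bool(
                self._rng_shield.random() < self.config.shield_avail_prob)
            self._push(time_s + self.config.shield_charge_s, "shield_gate", {})
            self._push(time_s + self.config.cs_duration_s, "cs_end", {})
            return [self._emit("cs_onset", cs_type=cs["type"])]
        if tag == "shield_gate":
            cs = self._cs
            if cs["available"]:
                cs["offered"] = True
                return [self._emit("shield_offered", cs_type=cs["type"])]
            return [self._emit("shield_unavailable", cs_type=cs["type"])]
        if tag == "cs_end":
            cs = self._cs
            batch = []
            if cs["type"] == "CS+" and not cs["shield_active"]:
                loss = _round_half_up(self.config.attack_fraction * max(self.points, 0))
                batch.append(self._emit("attack", cs_type="CS+", points_delta=-loss))
            batch.append(self._emit("cs_offset", cs_type=cs["type"]))
            self._cs = None
            return batch
        raise RuntimeError(f"unknown scheduled tag {tag!r}")  # pragma: no cover

    def end_block(self) -> list[Event]:
        """Drain remaining scheduled events and close the block."""
        batch = []
        while self._schedule:
            batch.extend(self.process_next_scheduled())
        self.clock = max(self.clock, self.config.block_duration_s)
        batch.append(self._emit("block_end"))
        return batch


def simulate_session(config: TaskConfig, policy: Policy, seed: int,
                     participant_id: str = "p0",
                     block_hook=None) -> EventLog:
    """Run a full session (pre-punishment then punishment blocks).

    Identical ``(config, policy, seed)`` produce an identical event log.  The
    policy is consulted for its next timed action; whenever an engine event
    lands first, the policy is shown the event batch and asked again, so its
    plans can react to cues, shield offers and outcomes.

    ``block_hook(block_index, phase)``, if given, runs after each block ends
    (used by the cohort generator to collect post-block self-reports).
    """
    engine = TaskEngine(config, seed=seed, participant_id=participant_id)
    phases = ["pre"] * config.n_pre_blocks + ["punish"] * config.n_punish_blocks
    for block_index, phase in enumerate(phases, start=1):
        engine.start_block(block_index, phase)
        policy.begin_block(block_index, phase)
        last_action_t = -math.inf
        while True:
            ns = engine.next_scheduled_time()
            act = policy.next_action(engine.observation())
            if act is None:
                if ns is None:
                    break
                policy.observe(engine.process_next_scheduled())
                continue
            t_act, kind, arg = act
            if t_act < last_action_t:
                raise ValueError(
                    f"policy action times must be nondecreasing ({t_act} < {last_action_t})")
            if ns is not None and ns <= t_act:
                policy.observe(engine.process_next_scheduled())
                continue
            if ns is None and t_act >= config.block_duration_s:
                break  # trading suspended and nothing left to resolve
            last_action_t = t_act
            if kind == ACTION_CLICK:
                policy.observe(engine.resolve_click(arg, t_act))
            elif kind == ACTION_SHIELD:
                policy.observe(engine.activate_shield(t_act))
            elif kind == ACTION_WAIT:
                engine.clock = max(engine.clock, t_act)
            else:
                raise ValueError(f"unknown policy action {kind!r}")
        policy.observe(engine.end_block())
        if block_hook is not None:
            block_hook(block_index, phase)
    return engine.log
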