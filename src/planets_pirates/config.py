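"""Task configuration for the planets-and-pirates conditioned-punishment game.

The defaults reproduce the published schedule: two 3-minute pre-punishment
blocks in which clicks on either planet start a 2 s trade countdown that pays
+100 points with probability 0.5, followed by three punishment blocks in
which the punished planet (R1) additionally triggers a 6 s danger cue (CS+,
20% per eligible click, 1.5 s onset delay) ending in an attack that removes
20% of the current point total, while the safe planet (R2) triggers an inert
cue (CS-) on the same schedule.  On a random half of cue presentations a
shield becomes available 3 s after cue onset; activating it costs 50 points
and prevents the attack but suspends trading until the cue ends.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

PLANETS = ("R1", "R2")
CS_PLUS = "CS+"
CS_MINUS = "CS-"


@dataclass(frozen=True)
class TaskConfig:
    block_duration_s: float = 180.0
    n_pre_blocks: int = 2
    n_punish_blocks: int = 3
    reward_prob: float = 0.5
    reward_points: int = 100
    trade_countdown_s: float = 2.0
    cs_prob: float = 0.2
    cs_delay_s: float = 1.5
    cs_duration_s: float = 6.0
    attack_fraction: float = 0.2
    shield_avail_prob: float = 0.5
    shield_charge_s: float = 3.0
    shield_cost_points: int = 50
    punished_planet: str = "R1"
    cs_plus_identity: str = "ship_type_I"
    side_assignment: str = "left"

    def __post_init__(self) -> None:
        for name in ("reward_prob", "cs_prob", "shield_avail_prob", "attack_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("block_duration_s", "trade_countdown_s", "cs_delay_s",
                     "cs_duration_s", "shield_charge_s"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if not self.shield_charge_s < self.cs_duration_s:
            raise ValueError("shield_charge_s must be smaller than cs_duration_s")
        if self.n_pre_blocks < 0 or self.n_punish_blocks < 0:
            raise ValueError("block counts must be non-negative")
        if self.punished_planet not in PLANETS:
            raise ValueError(f"punished_planet must be one of {PLANETS}")
        if self.side_assignment not in ("left", "right"):
            raise ValueError("side_assignment must be 'left' or 'right'")

    @property
    def n_blocks(self) -> int:
        return self.n_pre_blocks + self.n_punish_blocks

    def cs_type_for(self, planet: str) -> str:
        """Which cue a given planet's clicks can trigger in the punishment phase."""
        return CS_PLUS if planet == self.punished_planet else CS_MINUS

    def replace(self, **changes) -> "TaskConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown TaskConfig fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TaskConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "TaskConfig":
        """The standard schedule shipped with the package (data/task_defaults.yaml)."""
        text = resources.files("planets_pirates.data").joinpath("task_defaults.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate + analyze)."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_participants: int = 135
    sensitive_fraction: float = 0.32
    param_dispersion: float = 0.15
    seed: int = 0
    suppression_formula: str = "standard"
    k_values: tuple[int, ...] = (2, 3, 4)
    p_enter: float = 0.05
    p_remove: float = 0.10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.sensitive_fraction <= 1.0:
            raise ValueError("sensitive_fraction must be in [0, 1]")
        if self.suppression_formula not in ("standard", "literal"):
            raise ValueError("suppression_formula must be 'standard' or 'literal'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["task"] = self.task.to_dict()
        d["k_values"] = list(self.k_values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d and isinstance(d["task"], dict):
            d["task"] = TaskConfig.from_dict(d["task"])
        if "k_values" in d:
            d["k_values"] = tuple(d["k_values"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
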