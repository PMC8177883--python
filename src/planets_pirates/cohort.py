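"""Synthetic cohort generation: simulate many agents, collect their event
logs, self-reports and questionnaire stubs, and record a manifest of true
generative parameters for recovery testing.

A cohort directory contains::

    events.csv          tidy event log, one row per event
    self_reports.csv    one row per participant x block
    questionnaires.csv  catch-question correctness + generic subscale scores
    manifest.json       true archetypes, parameters, seeds, config hash
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import (AgentParams, AgentPolicy, generate_self_report,
                     jitter_params, make_agent)
from .config import TaskConfig
from .engine import simulate_session
from .events import EventLog, logs_to_dataframe

QUESTIONNAIRE_SUBSCALES = (
    "dass_depression", "dass_anxiety", "dass_stress",
    "bis11_impulsivity", "bis", "bas",
    "ipip_extraversion", "ipip_agreeableness", "ipip_conscientiousness",
    "ipip_neuroticism", "ipip_openness",
    "attribution_responsibility",
)


@dataclass
class Participant:
    participant_id: str
    archetype: str
    params: AgentParams
    log: EventLog
    self_reports: pd.DataFrame
    questionnaire: dict


@dataclass
class Cohort:
    participants: list[Participant] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.participants)

    def events_frame(self) -> pd.DataFrame:
        return logs_to_dataframe(p.log for p in self.participants)

    def self_reports_frame(self) -> pd.DataFrame:
        frames = []
        for p in self.participants:
            df = p.self_reports.copy()
            df.insert(0, "participant_id", p.participant_id)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["participant_id", "block", "phase"])
        return pd.concat(frames, ignore_index=True)

    def questionnaires_frame(self) -> pd.DataFrame:
        rows = [{"participant_id": p.participant_id, **p.questionnaire}
                for p in self.participants]
        cols = (["participant_id", "catch1_correct", "catch2_correct"]
                + list(QUESTIONNAIRE_SUBSCALES))
        return pd.DataFrame(rows, columns=cols)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.events_frame().to_csv(out / "events.csv", index=False)
        self.self_reports_frame().to_csv(out / "self_reports.csv", index=False)
        self.questionnaires_frame().to_csv(out / "questionnaires.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def _questionnaire_stub(params: AgentParams, rng: np.random.Generator) -> dict:
    row = {
        "catch1_correct": bool(rng.random() >= params.catch_fail_prob),
        "catch2_correct": bool(rng.random() >= params.catch_fail_prob),
    }
    for sub in QUESTIONNAIRE_SUBSCALES:
        row[sub] = float(np.clip(rng.normal(50.0, 10.0), 0.0, 100.0))
    return row


def generate_participant(participant_id: str, archetype: str, params: AgentParams,
                         config: TaskConfig, seed: int) -> Participant:
    """Simulate one agent's full session plus post-block reports."""
    ss = np.random.SeedSequence([seed])
    s_policy, s_report, s_quest, s_engine = ss.spawn(4)
    policy = AgentPolicy(params, np.random.default_rng(s_policy))
    report_rng = np.random.default_rng(s_report)
    engine_seed = int(s_engine.generate_state(1, np.uint32)[0]) % (2**31)

    # Reports are collected at each block end so they reflect the agent's
    # beliefs at that point in training, as in the real task.
    reports: list[dict] = []

    def _report(block_index: int, phase: str) -> None:
        reports.append(generate_self_report(policy, block_index, phase, report_rng))

    log = simulate_session(config, policy, seed=engine_seed,
                           participant_id=participant_id, block_hook=_report)

    return Participant(
        participant_id=participant_id,
        archetype=archetype,
        params=params,
        log=log,
        self_reports=pd.DataFrame(reports),
        questionnaire=_questionnaire_stub(params, np.random.default_rng(s_quest)),
    )


def generate_cohort(n: int, sensitive_fraction: float, param_dispersion: float = 0.15,
                    seed: int = 0, config: TaskConfig | None = None,
                    overrides: dict | None = None) -> Cohort:
    """Generate ``n`` synthetic participants with a bimodal archetype mixture.

    Exactly ``round(n * sensitive_fraction)`` agents are sensitive; archetype
    order is shuffled deterministically by ``seed``.  Per-participant
    parameters are jittered around the archetype defaults with relative
    dispersion ``param_dispersion``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= sensitive_fraction <= 1.0:
        raise ValueError("sensitive_fraction must be in [0, 1]")
    config = config or TaskConfig()
    master = np.random.SeedSequence(seed)
    rng = np.random.default_rng(master.spawn(1)[0])
    n_sensitive = int(round(n * sensitive_fraction))
    archetypes = np.array(["sensitive"] * n_sensitive
                          + ["insensitive"] * (n - n_sensitive))
    rng.shuffle(archetypes)

    cohort = Cohort()
    manifest_parts = []
    width = max(3, len(str(max(n, 1))))
    for i, archetype in enumerate(archetypes):
        pid = f"p{i:0{width}d}"
        pseed = int(np.random.SeedSequence([seed, 1000 + i]).generate_state(1, np.uint32)[0]) % (2**31)
        base = make_agent(str(archetype), overrides)
        params = jitter_params(base, param_dispersion,
                               np.random.default_rng(np.random.SeedSequence([seed, 2000 + i])))
        participant = generate_participant(pid, str(archetype), params, config, pseed)
        cohort.participants.append(participant)
        manifest_parts.append({
            "participant_id": pid,
            "archetype": str(archetype),
            "seed": pseed,
            "params": params.to_dict(),
        })

    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    cohort.manifest = {
        "n": n,
        "sensitive_fraction": sensitive_fraction,
        "param_dispersion": param_dispersion,
        "seed": seed,
        "config": config.to_dict(),
        "config_sha1": hashlib.sha1(cfg_json.encode()).hexdigest(),
        "generative_model": {
            "planet_choice": "softmax over Q = w_reward*E[reward] - w_punish*kappa.V*loss",
            "clicking": "exponential inter-click intervals, rate scaled by (1 - gain*V) during cues",
            "instrumental_learning": "delta rule on kappa[(planet, cue)] from cue-eligible clicks",
            "pavlovian_learning": "delta rule on V[cue] from unshielded cue outcomes",
            "shield_policy": "logistic(bias + slope*V[cue]) per offered shield",
            "reports": "truncated-normal noise around 100*kappa / 100*V; direct = capped chain",
        },
        "participants": manifest_parts,
    }
    return cohort


def read_cohort_dir(path: str | Path) -> dict:
    """Load a written cohort directory into dataframes + manifest."""
    path = Path(path)
    out = {
        "events": pd.read_csv(path / "events.csv") if (path / "events.csv").exists() else None,
        "self_reports": pd.read_csv(path / "self_reports.csv"),
        "questionnaires": pd.read_csv(path / "questionnaires.csv"),
        "manifest": json.loads((path / "manifest.json").read_text()),
    }
    if out["events"] is None:
        raise FileNotFoundError(f"no events.csv in {path}")
    return out
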