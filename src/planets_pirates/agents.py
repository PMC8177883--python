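"""Generative agents for synthetic task cohorts.

The cohort generator needs participants whose behaviour and self-reports
carry the statistical structure the analysis pipeline is designed to detect:
a bimodal split between a *sensitive* archetype that learns the instrumental
response->cue contingency and an *insensitive* archetype that does not, with
everything else (reward seeking, Pavlovian cue learning, shield policy,
report noise) identical between archetypes.

The agent is deliberately simple and is not a cognitive model of human
participants.  It clicks at exponential inter-click intervals, chooses
planets by a softmax over learned action values, suppresses clicking in
proportion to the learned aversive value of a visible cue, activates offered
shields with a logistic policy on that value, and reports noisy readouts of
its own internal contingency estimates after each block:

* ``kappa[(R, CS)]`` -- believed probability that a click on planet ``R``
  triggers cue ``CS``; updated toward the experienced trigger frequency at
  rate ``alpha_instr`` on every cue-eligible click.
* ``V[CS]`` -- believed probability that cue ``CS`` ends in an attack;
  delta-rule update at rate ``alpha_pav`` from unshielded cue outcomes.

Self-reported likelihoods are ``100*kappa`` and ``100*V`` plus
truncated-normal rating noise, and the *direct* response->attack report is
the capped chain product of the agent's own estimates — so at zero noise the
direct report equals the chained estimate exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
import numpy as np
from scipy import stats as sps

from .config import PLANETS, CS_PLUS, CS_MINUS
from .engine import BasePolicy, Observation, ACTION_CLICK, ACTION_SHIELD
from .events import Event

ARCHETYPES = ("sensitive", "insensitive")

#: nominal attack magnitude (points) used in the action-value computation;
#: roughly the loss from one attack at a typical mid-session point total.
NOMINAL_LOSS_POINTS = 200.0

#: expected points per click from trading (reward_prob * reward_points).
NOMINAL_REWARD_POINTS = 50.0

#: population mean of the prior response->cue contingency belief
#: (undiscriminated: the same prior applies to every response/cue pair).
KAPPA_PRIOR = 0.25

#: population mean of the prior aversive value of either cue.
V_PRIOR = 0.1

#: fixed motor delay between a shield offer and the agent's press.
SHIELD_REACTION_S = 0.5


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant."""

    base_click_rate: float = 60.0     # clicks / min during cue-free play
    softmax_beta: float = 0.07        # inverse temperature on point-valued Q
    alpha_instr: float = 0.2          # response->cue learning fidelity
    alpha_pav: float = 0.35           # cue->attack delta-rule rate
    w_reward: float = 1.0             # weight on expected reward points
    w_punish: float = 1.0             # weight on expected punishment points
    suppression_gain: float = 0.6     # click-rate reduction per unit cue value
    shield_bias: float = -2.0         # logistic shield-policy intercept
    shield_slope: float = 4.0         # logistic slope on cue value
    report_noise_sd: float = 10.0     # rating points
    rt_mean_s: float = 6.0            # mean response time per check screen
    rt_sd_s: float = 2.0
    catch_fail_prob: float = 0.02     # chance of failing a catch question
    kappa_prior_sd: float = 0.10      # between-subject sd of the contingency prior
    v_prior_sd: float = 0.05          # between-subject sd of the cue-value prior
    report_gain_sd: float = 0.25      # between-subject sd of the report scale gain

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_instr <= 1.0:
            raise ValueError("alpha_instr must be in [0, 1]")
        if not 0.0 <= self.alpha_pav <= 1.0:
            raise ValueError("alpha_pav must be in [0, 1]")
        if self.base_click_rate < 0:
            raise ValueError("base_click_rate must be >= 0")
        if self.report_noise_sd < 0:
            raise ValueError("report_noise_sd must be >= 0")
        if not 0.0 <= self.catch_fail_prob <= 1.0:
            raise ValueError("catch_fail_prob must be in [0, 1]")

    def replace(self, **changes) -> "AgentParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Archetypes differ ONLY in instrumental learning fidelity.
_ARCHETYPE_DEFAULTS = {
    "sensitive": AgentParams(),
    "insensitive": AgentParams(alpha_instr=0.0),
}


def make_agent(archetype: str, overrides: dict | None = None,
               seed: int | None = None) -> AgentParams:
    """Build agent parameters for an archetype, with optional field overrides."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"archetype must be one of {ARCHETYPES}, got {archetype!r}")
    params = _ARCHETYPE_DEFAULTS[archetype]
    if overrides:
        params = params.replace(**overrides)
    return params


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


class AgentPolicy(BasePolicy):
    """Reactive policy wrapping :class:`AgentParams`; learns across blocks."""

    def __init__(self, params: AgentParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        # Idiosyncratic prior beliefs: one contingency prior shared by every
        # response/cue pair (so priors alone induce no response bias) and one
        # shared cue-value prior.  Between-subject spread in these priors is
        # what gives self-reports realistic inter-individual variance.
        kappa0 = float(np.clip(KAPPA_PRIOR + params.kappa_prior_sd * rng.standard_normal(),
                               0.02, 0.75))
        v0 = float(np.clip(V_PRIOR + params.v_prior_sd * rng.standard_normal(), 0.0, 1.0))
        self.kappa = {(p, cs): kappa0 for p in PLANETS for cs in (CS_PLUS, CS_MINUS)}
        self.V = {CS_PLUS: v0, CS_MINUS: v0}
        self.kappa_prior = kappa0
        self.v_prior = v0
        # Subjective mapping from internal probabilities to the 0-100 rating
        # scale: each agent applies a personal gain per link type, used
        # consistently for link reports AND the direct chained report, so the
        # chain identity survives the distortion.
        self.kappa_gain = float(np.clip(1.0 + params.report_gain_sd * rng.standard_normal(),
                                        0.3, 2.0))
        self.v_gain = float(np.clip(1.0 + params.report_gain_sd * rng.standard_normal(),
                                    0.3, 2.0))
        self._eligible_clicks = {p: 0 for p in PLANETS}
        self._trigger_counts = {k: 0 for k in self.kappa}
        self._phase = "pre"
        self._active_cs: str | None = None
        self._cs_pending = False
        self._shield_active = False
        self._shield_plan: float | None = None
        self._next_click_t = 0.0
        self._next_planet = "R1"

    # ---- learned quantities -------------------------------------------

    def reported_kappa(self) -> dict:
        """Response->cue beliefs on the agent's subjective reporting scale."""
        return {k: min(1.0, self.kappa_gain * v) for k, v in self.kappa.items()}

    def reported_V(self) -> dict:
        """Cue->attack beliefs on the agent's subjective reporting scale."""
        return {k: min(1.0, self.v_gain * v) for k, v in self.V.items()}

    def q_values(self) -> dict:
        q = {}
        for p in PLANETS:
            penalty = (self.kappa[(p, CS_PLUS)] * self.V[CS_PLUS]
                       + self.kappa[(p, CS_MINUS)] * self.V[CS_MINUS]) * NOMINAL_LOSS_POINTS
            q[p] = (self.params.w_reward * NOMINAL_REWARD_POINTS
                    - self.params.w_punish * penalty)
        return q

    def _choose_planet(self) -> str:
        q = self.q_values()
        z = self.params.softmax_beta * np.array([q[p] for p in PLANETS])
        z -= z.max()
        probs = np.exp(z)
        probs /= probs.sum()
        return PLANETS[int(self.rng.choice(len(PLANETS), p=probs))]

    def _click_rate_per_s(self) -> float:
        rate = self.params.base_click_rate / 60.0
        if self._active_cs is not None:
            rate *= max(0.0, 1.0 - self.params.suppression_gain * self.V[self._active_cs])
        return rate

    def _schedule_next_click(self, now: float) -> None:
        rate = self._click_rate_per_s()
        if rate <= 0:
            self._next_click_t = float("inf")
            return
        self._next_click_t = now + self.rng.exponential(1.0 / rate)
        self._next_planet = self._choose_planet()

    # ---- policy protocol ----------------------------------------------

    def begin_block(self, block_index: int, phase: str) -> None:
        self._phase = phase
        self._active_cs = None
        self._cs_pending = False
        self._shield_active = False
        self._shield_plan = None
        self._schedule_next_click(0.0)

    def next_action(self, obs: Observation):
        if self._shield_plan is not None:
            return (self._shield_plan, ACTION_SHIELD, None)
        if not obs.trading_open and obs.cs_type is None:
            return None
        if self._next_click_t == float("inf"):
            return None
        # a plan made before an intervening action (e.g. a shield press) may
        # lie in the past; carry it out now rather than rewinding the clock
        return (max(self._next_click_t, obs.time_s), ACTION_CLICK, self._next_planet)

    def observe(self, events: list[Event]) -> None:
        clicked = [e for e in events if e.kind == "click"]
        triggered = {e.cs_type for e in events if e.kind == "cs_trigger"}
        for e in clicked:
            # Instrumental update on cue-eligible clicks only: kappa moves
            # toward the running experienced trigger frequency at rate
            # alpha_instr, so the estimate stabilises as evidence accrues
            # instead of random-walking with each individual outcome.
            if self._phase == "punish" and self._active_cs is None and not self._cs_pending:
                a = self.params.alpha_instr
                self._eligible_clicks[e.planet] += 1
                for cs in (CS_PLUS, CS_MINUS):
                    key = (e.planet, cs)
                    if cs in triggered:
                        self._trigger_counts[key] += 1
                    freq = self._trigger_counts[key] / self._eligible_clicks[e.planet]
                    self.kappa[key] += a * (freq - self.kappa[key])
        attack_seen = any(e.kind == "attack" for e in events)
        for e in events:
            if e.kind == "cs_trigger":
                self._cs_pending = True
            elif e.kind == "cs_onset":
                self._cs_pending = False
                self._active_cs = e.cs_type
            elif e.kind == "shield_offered":
                p_act = _sigmoid(self.params.shield_bias
                                 + self.params.shield_slope * self.V[e.cs_type])
                if self.rng.random() < p_act:
                    self._shield_plan = e.time_s + SHIELD_REACTION_S
            elif e.kind == "shield_activated":
                self._shield_plan = None
                self._shield_active = True
            elif e.kind == "cs_offset":
                if not self._shield_active:
                    target = 1.0 if attack_seen else 0.0
                    self.V[e.cs_type] += self.params.alpha_pav * (target - self.V[e.cs_type])
                self._active_cs = None
                self._shield_active = False
                self._shield_plan = None
        if clicked:
            self._schedule_next_click(clicked[-1].time_s)


# ---- self reports -----------------------------------------------------


def _noisy_rating(clean: float, sd: float, rng: np.random.Generator) -> float:
    """A rating in [0, 100]: truncated-normal noise around the clean value."""
    clean = float(np.clip(clean, 0.0, 100.0))
    if sd == 0:
        return clean
    a, b = (0.0 - clean) / sd, (100.0 - clean) / sd
    return float(sps.truncnorm.rvs(a, b, loc=clean, scale=sd, random_state=rng))


def chain_from_beliefs(kappa: dict, V: dict, planet: str) -> float:
    """Capped chained response->attack probability (percent) from agent beliefs."""
    raw = (kappa[(planet, CS_PLUS)] * V[CS_PLUS]
           + kappa[(planet, CS_MINUS)] * V[CS_MINUS]) * 100.0
    return min(100.0, raw)


def generate_self_report(policy: AgentPolicy, block_index: int, phase: str,
                         rng: np.random.Generator) -> dict:
    """Post-block check-screen responses as one flat record.

    Valuations and likelihood inferences are noisy readouts of the agent's
    internal estimates; pre-punishment blocks contain only the reward/planet
    items.  Response times are truncated-normal on (0, inf), one mean per
    check screen.
    """
    p = policy.params
    sd = p.report_noise_sd
    q = policy.q_values()
    row: dict = {"block": block_index, "phase": phase}
    row["val_reward"] = _noisy_rating(80.0, sd, rng)
    for planet in PLANETS:
        row[f"val_{planet}"] = _noisy_rating(50.0 + 0.5 * (q[planet] - NOMINAL_REWARD_POINTS),
                                             sd, rng)
        row[f"inf_{planet}_reward"] = _noisy_rating(100.0 * 0.5, sd, rng)
        row[f"conf_{planet}_reward"] = _noisy_rating(70.0, sd, rng)
    screens = [f"rt_{s}" for s in ("value", "R1", "R2")]
    if phase == "punish":
        kap, val = policy.reported_kappa(), policy.reported_V()
        row["val_attack"] = _noisy_rating(15.0, sd, rng)
        for cs, tag in ((CS_PLUS, "CSplus"), (CS_MINUS, "CSminus")):
            row[f"val_{tag}"] = _noisy_rating(50.0 - 40.0 * policy.V[cs], sd, rng)
            row[f"inf_{tag}_attack"] = _noisy_rating(100.0 * val[cs], sd, rng)
            row[f"conf_{tag}_attack"] = _noisy_rating(70.0, sd, rng)
        for planet in PLANETS:
            for cs, tag in ((CS_PLUS, "CSplus"), (CS_MINUS, "CSminus")):
                row[f"inf_{planet}_{tag}"] = _noisy_rating(100.0 * kap[(planet, cs)],
                                                           sd, rng)
                row[f"conf_{planet}_{tag}"] = _noisy_rating(70.0, sd, rng)
            row[f"inf_{planet}_attack"] = _noisy_rating(
                chain_from_beliefs(kap, val, planet), sd, rng)
            row[f"conf_{planet}_attack"] = _noisy_rating(70.0, sd, rng)
        screens += ["rt_CSplus", "rt_CSminus"]
    for s in screens:
        a = (0.0 - p.rt_mean_s) / p.rt_sd_s
        row[s] = float(sps.truncnorm.rvs(a, np.inf, loc=p.rt_mean_s, scale=p.rt_sd_s,
                                         random_state=rng))
    return row


def jitter_params(params: AgentParams, dispersion: float,
                  rng: np.random.Generator) -> AgentParams:
    """Per-participant parameter variation around an archetype.

    Rate- and scale-like parameters get multiplicative log-normal jitter;
    learning rates get proportional jitter clipped to [0, 1].  An exactly
    zero learning rate stays zero (the insensitive archetype's defining
    feature is the absence of instrumental learning, not a small rate).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")

    def mult(x: float) -> float:
        return float(x * np.exp(dispersion * rng.standard_normal()))

    def rate(x: float) -> float:
        if x == 0.0:
            return 0.0
        return float(np.clip(x * (1.0 + dispersion * rng.standard_normal()), 0.0, 1.0))

    return params.replace(
        base_click_rate=mult(params.base_click_rate),
        softmax_beta=mult(params.softmax_beta),
        alpha_instr=rate(params.alpha_instr),
        alpha_pav=rate(params.alpha_pav),
        suppression_gain=rate(params.suppression_gain),
        shield_bias=float(params.shield_bias + dispersion * rng.standard_normal()),
        shield_slope=mult(params.shield_slope),
        report_noise_sd=mult(params.report_noise_sd),
        rt_mean_s=mult(params.rt_mean_s),
        rt_sd_s=mult(params.rt_sd_s),
    )
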