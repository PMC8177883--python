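"""Task-engine contingency rules, hand-traced against the schedule."""

import numpy as np
import pytest

from planets_pirates import (TaskConfig, TaskEngine, simulate_session,
                             validate_event_log, NullPolicy, ScriptedClicker,
                             EventLog, Event)


def kinds(events):
    return [e.kind for e in events]


class TestConfig:
    def test_defaults_reproduce_schedule(self, default_config):
        c = default_config
        assert (c.block_duration_s, c.n_pre_blocks, c.n_punish_blocks) == (180.0, 2, 3)
        assert (c.reward_prob, c.reward_points, c.trade_countdown_s) == (0.5, 100, 2.0)
        assert (c.cs_prob, c.cs_delay_s, c.cs_duration_s) == (0.2, 1.5, 6.0)
        assert (c.attack_fraction, c.shield_avail_prob) == (0.2, 0.5)
        assert (c.shield_charge_s, c.shield_cost_points) == (3.0, 50)
        assert TaskConfig.default() == c

    @pytest.mark.parametrize("bad", [
        {"reward_prob": 1.5}, {"cs_prob": -0.1}, {"block_duration_s": 0},
        {"shield_charge_s": 7.0}, {"punished_planet": "R3"},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            TaskConfig(**bad)


class TestClickResolution:
    def test_forced_reward_trade(self):
        """A click starts a 2 s countdown; a successful roll pays +100."""
        eng = TaskEngine(TaskConfig(reward_prob=1.0), seed=0)
        eng.start_block(1, "pre")
        batch = eng.resolve_click("R1", 10.0)
        assert kinds(batch) == ["click", "trade_start"]
        assert batch[1].time_s == 10.0
        out = eng.process_next_scheduled()
        assert kinds(out) == ["reward"]
        assert out[0].time_s == 12.0 and out[0].points_delta == 100

    def test_forced_no_reward(self):
        eng = TaskEngine(TaskConfig(reward_prob=0.0), seed=0)
        eng.start_block(1, "pre")
        eng.resolve_click("R2", 5.0)
        out = eng.process_next_scheduled()
        assert kinds(out) == ["no_reward"] and out[0].points_delta == 0

    def test_click_during_countdown_starts_no_second_trade(self):
        eng = TaskEngine(TaskConfig(reward_prob=1.0), seed=0)
        eng.start_block(1, "pre")
        eng.resolve_click("R1", 10.0)
        batch = eng.resolve_click("R1", 10.5)
        assert kinds(batch) == ["click"]

    def test_countdowns_independent_across_planets(self):
        eng = TaskEngine(TaskConfig(reward_prob=1.0), seed=0)
        eng.start_block(1, "pre")
        eng.resolve_click("R1", 10.0)
        batch = eng.resolve_click("R2", 10.5)
        assert kinds(batch) == ["click", "trade_start"]

    def test_unknown_planet_rejected(self):
        eng = TaskEngine(TaskConfig(), seed=0)
        eng.start_block(1, "pre")
        with pytest.raises(ValueError, match="planet"):
            eng.resolve_click("R3", 1.0)

    def test_backwards_timestamp_rejected(self):
        eng = TaskEngine(TaskConfig(), seed=0)
        eng.start_block(1, "pre")
        eng.resolve_click("R1", 10.0)
        with pytest.raises(ValueError, match="precede"):
            eng.resolve_click("R1", 9.0)


class TestCsScheduling:
    def test_forced_cs_trigger_and_single_pending_rule(self):
        """Punished-planet click triggers CS+ with 1.5 s onset delay; a second
        click while the cue is pending rolls no new cue."""
        eng = TaskEngine(TaskConfig(cs_prob=1.0, reward_prob=0.0), seed=0)
        eng.start_block(1, "punish")
        batch = eng.resolve_click("R1", 20.0)
        assert kinds(batch) == ["click", "trade_start", "cs_trigger"]
        assert batch[2].cs_type == "CS+"
        batch2 = eng.resolve_click("R1", 20.5)
        assert "cs_trigger" not in kinds(batch2)
        # drain: trade outcome @22, onset @21.5 first
        onset = eng.process_next_scheduled()
        assert kinds(onset) == ["cs_onset"] and onset[0].time_s == 21.5

    def test_safe_planet_triggers_cs_minus(self):
        eng = TaskEngine(TaskConfig(cs_prob=1.0, reward_prob=0.0), seed=0)
        eng.start_block(1, "punish")
        batch = eng.resolve_click("R2", 5.0)
        assert batch[-1].kind == "cs_trigger" and batch[-1].cs_type == "CS-"

    def test_no_cs_roll_in_pre_phase(self):
        eng = TaskEngine(TaskConfig(cs_prob=1.0), seed=0)
        eng.start_block(1, "pre")
        assert "cs_trigger" not in kinds(eng.resolve_click("R1", 5.0))


def run_forced_cs_episode(points_start=0, avail=0.0, cs_planet="R1",
                          activate_at=None, reward_prob=0.0):
    """Drive one forced cue episode; returns (engine, all events)."""
    cfg = TaskConfig(cs_prob=1.0, reward_prob=reward_prob, shield_avail_prob=avail)
    eng = TaskEngine(cfg, seed=0)
    eng.start_block(1, "punish")
    if points_start:
        eng._emit("reward", points_delta=points_start)  # seed the bank
    events = list(eng.resolve_click(cs_planet, 20.0))
    while eng.next_scheduled_time() is not None:
        if activate_at is not None and eng._cs is not None and eng._cs["offered"] \
                and not eng._cs["shield_active"] \
                and activate_at < eng.next_scheduled_time():
            events.extend(eng.activate_shield(activate_at))
            activate_at = None
            continue
        events.extend(eng.process_next_scheduled())
    return eng, events


class TestCsEpisode:
    def test_unshielded_cs_plus_attacks_20_percent(self):
        """Attack at onset+6 s removes 20% of the current point bank."""
        eng, events = run_forced_cs_episode(points_start=1000, avail=0.0)
        attack = next(e for e in events if e.kind == "attack")
        assert attack.points_delta == -200
        assert attack.time_s == pytest.approx(27.5)  # 20 + 1.5 + 6
        assert any(e.kind == "shield_unavailable" and e.time_s == pytest.approx(24.5)
                   for e in events)
        offset = next(e for e in events if e.kind == "cs_offset")
        assert offset.time_s == pytest.approx(27.5)

    def test_cs_minus_never_attacks(self):
        eng, events = run_forced_cs_episode(points_start=1000, avail=0.0,
                                            cs_planet="R2")
        assert not any(e.kind == "attack" for e in events)
        assert any(e.kind == "cs_offset" and e.cs_type == "CS-" for e in events)

    def test_shielded_cs_plus_no_attack_only_shield_cost(self):
        eng, events = run_forced_cs_episode(points_start=1000, avail=1.0,
                                            activate_at=24.7)
        assert not any(e.kind == "attack" for e in events)
        sh = next(e for e in events if e.kind == "shield_activated")
        assert sh.points_delta == -50

    def test_attack_clamped_at_zero_points(self):
        """Attacks never add points: with an empty bank the loss is 0."""
        eng, events = run_forced_cs_episode(points_start=0, avail=0.0)
        attack = next(e for e in events if e.kind == "attack")
        assert attack.points_delta == 0

    def test_attack_on_negative_bank_deducts_nothing(self):
        cfg = TaskConfig(cs_prob=1.0, reward_prob=0.0, shield_avail_prob=0.0)
        eng = TaskEngine(cfg, seed=0)
        eng.start_block(1, "punish")
        eng._emit("shield_activated", points_delta=-50)  # bank below zero
        eng.resolve_click("R1", 20.0)
        events = []
        while eng.next_scheduled_time() is not None:
            events.extend(eng.process_next_scheduled())
        attack = next(e for e in events if e.kind == "attack")
        assert attack.points_delta == 0


class TestShield:
    def _engine_with_offer(self):
        cfg = TaskConfig(cs_prob=1.0, reward_prob=0.0, shield_avail_prob=1.0)
        eng = TaskEngine(cfg, seed=0)
        eng.start_block(1, "punish")
        eng.resolve_click("R1", 20.0)
        while not any(e.kind == "shield_offered" for e in eng.log):
            eng.process_next_scheduled()
        return eng

    def test_valid_activation_costs_50(self):
        eng = self._engine_with_offer()
        batch = eng.activate_shield(25.0)
        assert kinds(batch) == ["shield_activated"]
        assert batch[0].points_delta == -50

    def test_activation_without_offer_rejected(self):
        cfg = TaskConfig(cs_prob=1.0, reward_prob=0.0, shield_avail_prob=0.0)
        eng = TaskEngine(cfg, seed=0)
        eng.start_block(1, "punish")
        eng.resolve_click("R1", 20.0)
        eng.process_next_scheduled()   # onset
        eng.process_next_scheduled()   # shield_unavailable
        with pytest.raises(ValueError, match="no shield was offered"):
            eng.activate_shield(25.0)

    def test_double_activation_rejected(self):
        eng = self._engine_with_offer()
        eng.activate_shield(25.0)
        with pytest.raises(ValueError, match="already active"):
            eng.activate_shield(25.5)

    def test_activation_after_offset_rejected(self):
        eng = self._engine_with_offer()
        with pytest.raises(ValueError, match="after the CS ended"):
            eng.activate_shield(28.0)

    def test_clicks_during_active_shield_start_no_trade(self):
        """An active shield suspends trading for the rest of the cue."""
        eng = self._engine_with_offer()
        eng.activate_shield(25.0)
        batch = eng.resolve_click("R2", 25.5)
        assert kinds(batch) == ["click"]
        # after the cue ends trading resumes
        while eng.next_scheduled_time() is not None:
            eng.process_next_scheduled()
        batch = eng.resolve_click("R2", 30.0)
        assert "trade_start" in kinds(batch)


class TestSession:
    def test_null_policy_yields_only_block_boundaries(self, default_config):
        log = simulate_session(default_config, NullPolicy(), seed=0)
        assert kinds(log.events) == ["block_end"] * 5
        assert log.final_points() == 0

    def test_block_structure_and_phases(self, default_config):
        log = simulate_session(default_config, ScriptedClicker(2.0), seed=0)
        phases = {b: log.block_events(b)[0].phase for b in log.blocks()}
        assert phases == {1: "pre", 2: "pre", 3: "punish", 4: "punish", 5: "punish"}
        for b in log.blocks():
            end = log.block_events(b)[-1]
            assert end.kind == "block_end"
            assert end.time_s >= default_config.block_duration_s

    def test_simulator_output_is_valid(self, default_config):
        log = simulate_session(default_config, ScriptedClicker(0.4), seed=3)
        assert validate_event_log(log) == []

    def test_point_conservation(self, default_config):
        log = simulate_session(default_config, ScriptedClicker(0.4), seed=3)
        rewards = sum(e.points_delta for e in log if e.kind == "reward")
        shields = sum(e.points_delta for e in log if e.kind == "shield_activated")
        attacks = sum(e.points_delta for e in log if e.kind == "attack")
        assert log.final_points() == rewards + shields + attacks

    def test_determinism_byte_identical(self, default_config, tmp_path):
        a = simulate_session(default_config, ScriptedClicker(0.4), seed=11)
        b = simulate_session(default_config, ScriptedClicker(0.4), seed=11)
        a.to_jsonl(tmp_path / "a.jsonl")
        b.to_jsonl(tmp_path / "b.jsonl")
        assert (tmp_path / "a.jsonl").read_bytes() == (tmp_path / "b.jsonl").read_bytes()
        c = simulate_session(default_config, ScriptedClicker(0.4), seed=12)
        assert c.to_dataframe().to_csv() != a.to_dataframe().to_csv()

    def test_zero_cs_prob_matches_pre_phase_reward_rate(self):
        """With the cue probability at zero the punishment phase behaves like
        reward training: seed-matched reward event rates agree."""
        base = TaskConfig(n_pre_blocks=2, n_punish_blocks=0)
        log_pre = simulate_session(base, ScriptedClicker(0.5), seed=21)
        punished = TaskConfig(n_pre_blocks=0, n_punish_blocks=2, cs_prob=0.0)
        log_pun = simulate_session(punished, ScriptedClicker(0.5), seed=21)
        n_pre = sum(1 for e in log_pre if e.kind == "reward")
        n_pun = sum(1 for e in log_pun if e.kind == "reward")
        assert n_pre == n_pun
        assert not any(e.kind.startswith("cs") for e in log_pun)

    def test_contingency_calibration_99ci(self):
        """Empirical reward / CS / shield probabilities sit inside 99%
        binomial confidence bands of their programmed values."""
        cfg = TaskConfig(n_pre_blocks=0, n_punish_blocks=30)
        log = simulate_session(cfg, ScriptedClicker(0.25, ("R1",)), seed=5)
        trades = sum(1 for e in log if e.kind == "trade_start")
        rewards = sum(1 for e in log if e.kind == "reward")
        onsets = sum(1 for e in log if e.kind == "cs_onset")
        offers = sum(1 for e in log if e.kind == "shield_offered")
        for phat, p, n in [(rewards / trades, 0.5, trades),
                           (offers / onsets, 0.5, onsets)]:
            half = 2.576 * np.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < half, (phat, p, n)
        # CS probability per eligible click
        elig = trig = 0
        for b in log.blocks():
            evs = log.block_events(b)
            windows, cur = [], None
            for e in evs:
                if e.kind == "cs_trigger":
                    cur = [e.time_s, None]
                elif e.kind == "cs_offset":
                    cur[1] = e.time_s
                    windows.append(cur)
                    cur = None
            for e in evs:
                if e.kind == "click" and e.time_s < cfg.block_duration_s and \
                        not any(w[0] < e.time_s < w[1] for w in windows):
                    elig += 1
                elif e.kind == "cs_trigger":
                    trig += 1
        half = 2.576 * np.sqrt(0.2 * 0.8 / elig)
        assert elig >= 2500
        assert abs(trig / elig - 0.2) < half


class TestValidation:
    def test_overlapping_cs_reported(self):
        log = EventLog("x", [
            Event(1.0, 1, "punish", "cs_trigger", cs_type="CS+"),
            Event(2.5, 1, "punish", "cs_onset", cs_type="CS+"),
            Event(3.0, 1, "punish", "cs_trigger", cs_type="CS-"),
            Event(4.5, 1, "punish", "cs_onset", cs_type="CS-"),
        ])
        v = validate_event_log(log)
        assert any("only one CS" in msg for msg in v)

    def test_points_total_mismatch_reported(self):
        log = EventLog("x", [
            Event(1.0, 1, "pre", "reward", planet="R1", points_delta=100,
                  points_total=100),
            Event(2.0, 1, "pre", "reward", planet="R1", points_delta=100,
                  points_total=150),
        ])
        v = validate_event_log(log)
        assert any("cumulative" in msg for msg in v)

    def test_attack_during_shield_reported(self):
        log = EventLog("x", [
            Event(1.0, 1, "punish", "cs_trigger", cs_type="CS+"),
            Event(2.5, 1, "punish", "cs_onset", cs_type="CS+"),
            Event(5.5, 1, "punish", "shield_offered", cs_type="CS+"),
            Event(6.0, 1, "punish", "shield_activated", cs_type="CS+",
                  points_delta=-50, points_total=-50),
            Event(8.5, 1, "punish", "attack", cs_type="CS+", points_total=-50),
            Event(8.5, 1, "punish", "cs_offset", cs_type="CS+", points_total=-50),
        ])
        v = validate_event_log(log)
        assert any("despite active shield" in msg for msg in v)


class TestSerialisation:
    def test_jsonl_round_trip(self, default_config, tmp_path):
        log = simulate_session(default_config, ScriptedClicker(1.0), seed=2)
        log.to_jsonl(tmp_path / "log.jsonl")
        back = EventLog.from_jsonl(tmp_path / "log.jsonl")
        assert back == log

    def test_dataframe_round_trip(self, default_config):
        log = simulate_session(default_config, ScriptedClicker(1.0), seed=2)
        df = log.to_dataframe()
        assert list(df.columns) == ["participant_id", "block", "phase", "time_s",
                                    "kind", "planet", "cs_type", "points_delta",
                                    "points_total"]
        assert EventLog.from_dataframe(df) == log
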