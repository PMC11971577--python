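"""Session engine: phase semantics, lockout, alerts, determinism, replay."""

import math

import numpy as np
import pytest
from pydantic import ValidationError

from contactstim import (
    MockActuator,
    ReplayMismatchError,
    SessionConfig,
    TruncationError,
    config_hash,
    replay,
    response_frequency,
    run_session,
)
from contactstim.engine import SessionLog, Event
from contactstim.errors import LogParseError
from contactstim.simulate import default_session_config

from .conftest import contact_stream


def _cfg(phase, regions, **kw):
    base = default_session_config(phase_type=phase, rng_seed=0)
    return base.model_copy(update=kw) if kw else base


def continuous_touch(regions, duration=300.0, fps=10.0):
    n = int(duration * fps)
    return contact_stream([True] * n, regions, fps=fps)


def empty_stream(regions, duration=300.0, fps=10.0):
    n = int(duration * fps)
    return contact_stream([False] * n, regions, fps=fps)


class TestAlertSchedule:
    def test_fixed_draw_schedule(self, regions):
        """Contact-free session with a degenerate 35-s window -> alerts at
        35, 70, ..., 280 (eight events) and zero responses."""
        cfg = _cfg("baseline", regions, alert_window_s=(35.0, 35.0))
        log = run_session(cfg, empty_stream(regions))
        assert log.alert_times == [pytest.approx(35.0 * k) for k in range(1, 9)]
        assert response_frequency(log) == 0

    def test_alert_gap_at_least_window_min(self, regions):
        cfg = _cfg("baseline", regions, rng_seed=9)
        log = run_session(cfg, empty_stream(regions))
        gaps = np.diff([0.0] + log.alert_times)
        assert (gaps >= 30.0).all() and (gaps <= 40.0 + 1e-9).all()

    def test_no_alert_soon_after_response(self, regions):
        rng = np.random.default_rng(0)
        flags = (rng.uniform(size=3000) < 0.02).tolist()
        cfg = _cfg("baseline", regions, rng_seed=5)
        log = run_session(cfg, contact_stream(flags, regions))
        anchors = sorted(log.response_times + log.alert_times)
        for a in log.alert_times:
            prior = [t for t in anchors if t < a]
            if prior:
                assert a - max(prior) >= 30.0 - 1e-9


class TestLockoutAndResponses:
    def test_continuous_touch_max_rate(self, regions):
        """A hand resting on an object all session: one response per lockout
        period -> 30 responses at t = 0, 10, ..., 290 with stim after each."""
        cfg = _cfg("intervention", regions)
        log = run_session(cfg, continuous_touch(regions))
        assert log.response_times == [pytest.approx(10.0 * k) for k in range(30)]
        assert len(log.of_type("stim_on")) == 30
        assert len(log.of_type("stim_off")) == 30

    def test_response_frequency_counts(self, regions):
        cfg = _cfg("intervention", regions)
        log = run_session(cfg, continuous_touch(regions))
        assert response_frequency(log) == 30

    def test_structural_ceiling(self, regions):
        cfg = _cfg("intervention", regions)
        log = run_session(cfg, continuous_touch(regions))
        assert response_frequency(log) <= math.ceil(
            cfg.session_duration_s / cfg.lockout_s
        )

    def test_lockout_separates_responses(self, regions):
        rng = np.random.default_rng(12)
        flags = (rng.uniform(size=3000) < 0.3).tolist()
        cfg = _cfg("baseline", regions)
        log = run_session(cfg, contact_stream(flags, regions))
        gaps = np.diff(log.response_times)
        assert (gaps >= cfg.lockout_s - 1e-9).all()

    def test_contact_during_lockout_audited_not_counted(self, regions):
        # touch at t=0 (response), release, touch again at t=3 (inside lockout)
        flags = [True] * 10 + [False] * 10 + [True] * 10 + [False] * 2970
        cfg = _cfg("baseline", regions)
        log = run_session(cfg, contact_stream(flags, regions))
        ignored = log.of_type("contact_ignored")
        assert response_frequency(log) >= 1
        assert any(1.9 < e.t < 10.0 for e in ignored)
        assert all(e.t < cfg.session_duration_s for e in ignored)


class TestPhaseSemantics:
    def test_baseline_no_stimulation(self, regions):
        log = run_session(_cfg("baseline", regions), continuous_touch(regions))
        assert log.of_type("stim_on") == [] and log.of_type("stim_off") == []
        assert response_frequency(log) == 30

    def test_intervention_stim_per_response_truncated_at_end(self, regions):
        log = run_session(_cfg("intervention", regions), continuous_touch(regions))
        ons = log.of_type("stim_on")
        offs = log.of_type("stim_off")
        assert len(ons) == response_frequency(log)
        for on, off in zip(ons, offs):
            assert off.t <= on.t + 10.0 + 1e-9
            assert off.t <= 300.0
        total = sum(off.t - on.t for on, off in zip(ons, offs))
        assert total == pytest.approx(10.0 * 30, abs=1e-6)

    def test_control_continuous_stimulation(self, regions):
        """Control: stim_on at 0, changes every control_change_s, stim_off at
        session end; responses logged but never trigger stimulation."""
        cfg = _cfg("control", regions, control_change_s=60.0)
        log = run_session(cfg, continuous_touch(regions))
        assert [e.t for e in log.of_type("stim_on")] == [0.0]
        assert [e.t for e in log.of_type("stim_change")] == [60.0, 120.0, 180.0, 240.0]
        assert [e.t for e in log.of_type("stim_off")] == [300.0]
        assert response_frequency(log) == 30  # logged, not reinforced

    def test_log_structure_invariants(self, regions):
        for phase in ("baseline", "intervention", "control"):
            log = run_session(_cfg(phase, regions), continuous_touch(regions))
            assert log.events[0].type == "session_start" and log.events[0].t == 0.0
            assert log.events[-1].type == "session_end" and log.events[-1].t == 300.0
            ts = [e.t for e in log.events]
            assert ts == sorted(ts)


class TestDeterminismAndReplay:
    def test_identical_inputs_identical_logs(self, regions):
        rng = np.random.default_rng(21)
        flags = (rng.uniform(size=3000) < 0.05).tolist()
        cfg = _cfg("intervention", regions, rng_seed=77)
        log1 = run_session(cfg, contact_stream(flags, regions))
        log2 = run_session(cfg, contact_stream(flags, regions))
        assert log1 == log2

    def test_replay_hash_match_reproduces(self, regions, tmp_path):
        from contactstim.streams import write_frames_jsonl

        rng = np.random.default_rng(22)
        flags = (rng.uniform(size=3000) < 0.05).tolist()
        stream = contact_stream(flags, regions)
        cfg = _cfg("baseline", regions, rng_seed=5)
        original = run_session(cfg, stream)
        path = tmp_path / "frames.jsonl"
        write_frames_jsonl(path, stream)
        again = replay(path, cfg, reference=original)
        assert again.events == original.events

    def test_replay_refuses_config_mismatch(self, regions):
        cfg = _cfg("baseline", regions, rng_seed=5)
        log = run_session(cfg, empty_stream(regions))
        other = cfg.model_copy(update={"rng_seed": 6})
        with pytest.raises(ReplayMismatchError):
            replay(empty_stream(regions), other, reference=log)

    def test_different_seed_moves_alerts_not_responses(self, regions):
        rng = np.random.default_rng(23)
        flags = (rng.uniform(size=3000) < 0.05).tolist()
        log_a = run_session(_cfg("baseline", regions, rng_seed=1), contact_stream(flags, regions))
        log_b = run_session(_cfg("baseline", regions, rng_seed=2), contact_stream(flags, regions))
        assert log_a.response_times == log_b.response_times
        assert log_a.alert_times != log_b.alert_times

    def test_phase_swap_preserves_response_timestamps(self, regions):
        """The lockout applies in all phases, so swapping intervention for
        baseline changes stim events but not a single response time."""
        rng = np.random.default_rng(24)
        flags = (rng.uniform(size=3000) < 0.1).tolist()
        log_i = run_session(_cfg("intervention", regions), contact_stream(flags, regions))
        log_b = run_session(_cfg("baseline", regions), contact_stream(flags, regions))
        assert log_i.response_times == log_b.response_times
        assert log_b.of_type("stim_on") == []


class TestConfigAndErrors:
    def test_truncated_stream_raises_with_last_timestamp(self, regions):
        short = contact_stream([False] * 100, regions)  # 10 s of frames
        with pytest.raises(TruncationError) as err:
            run_session(_cfg("baseline", regions), short)
        assert err.value.last_covered_s == pytest.approx(9.9)

    def test_lockout_coupling_enforced(self, regions):
        with pytest.raises(ValidationError):
            SessionConfig(
                participant_id="p",
                regions=regions,
                stim_duration_s=10.0,
                lockout_s=5.0,
            )

    def test_lockout_defaults_to_stim_duration(self, regions):
        cfg = SessionConfig(participant_id="p", regions=regions, stim_duration_s=8.0)
        assert cfg.lockout_s == 8.0

    def test_alert_window_order_enforced(self, regions):
        with pytest.raises(ValidationError):
            SessionConfig(
                participant_id="p", regions=regions, alert_window_s=(40.0, 30.0)
            )

    def test_config_hash_stable_and_sensitive(self, regions):
        a = _cfg("baseline", regions)
        b = _cfg("baseline", regions)
        assert config_hash(a) == config_hash(b)
        assert config_hash(a) != config_hash(a.model_copy(update={"rng_seed": 1}))

    def test_response_frequency_rejects_malformed(self):
        with pytest.raises(LogParseError):
            response_frequency({"events": []})
        bad = SessionLog(header={}, events=[Event(0.0, "bogus_type", {})])
        with pytest.raises(LogParseError):
            response_frequency(bad)


def test_actuator_records_match_log_totals(regions):
    """Cross-check: stimulation time computed from mock actuator records
    equals the total computed from the event log."""
    actuator = MockActuator()
    cfg = default_session_config(phase_type="intervention", rng_seed=3)
    log = run_session(cfg, continuous_touch(regions), actuator=actuator)
    ons = log.of_type("stim_on")
    offs = log.of_type("stim_off")
    log_total = sum(off.t - on.t for on, off in zip(ons, offs))
    stim_records = [r for r in actuator.records if r.stimulus_id == "preferred_music"]
    assert sum(r.playtime_s for r in stim_records) == pytest.approx(log_total)
    assert len(stim_records) == len(ons)
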