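"""Schedule-engine contracts, curricula, devaluation assay, and the
trace generator."""

import math

import numpy as np
import pytest

from pallidoseek import (AgentParams, BehavioralEvent, EventType,
                         NeuralGenParams, ScheduleKind, ScheduleSpec,
                         SessionRecord, calibrate_schedule, compute_dff,
                         generate_trace, kernel_peak_lag_s,
                         simulate_curriculum, simulate_devaluation_pair,
                         simulate_session)

QUIET = AgentParams(nose_poke_rate_hz=1.0, inactive_rate_hz=0.0,
                    magazine_check_rate_hz=0.0)


def active_pokes(session):
    return [e for e in session.events
            if e.event_type is EventType.NOSE_POKE_ACTIVE]


class TestScheduleContracts:
    def test_ratio_one_rewards_every_poke(self):
        spec = ScheduleSpec(kind=ScheduleKind.RR, value=1, session_cap_s=120)
        s = simulate_session(spec, QUIET, seed=1)
        pokes = active_pokes(s)
        assert pokes and all(p.rewarded for p in pokes)

    def test_fast_responder_hits_reward_cap(self):
        # RR2 at a deterministic 2 pokes/s: ~1 reward/s, cap of 60 binds
        spec = ScheduleSpec(kind=ScheduleKind.RR, value=2)
        agent = AgentParams(nose_poke_rate_hz=2.0, deterministic_pokes=True,
                            inactive_rate_hz=0.0, magazine_check_rate_hz=0.0)
        s = simulate_session(spec, agent, seed=2)
        assert s.termination == "reward_cap"
        assert s.n_rewards == 60
        assert s.duration_s < 1800

    def test_slow_responder_hits_time_cap(self):
        spec = ScheduleSpec(kind=ScheduleKind.RI, value=60)
        agent = AgentParams(nose_poke_rate_hz=1 / 200, inactive_rate_hz=0.0,
                            magazine_check_rate_hz=0.0)
        s = simulate_session(spec, agent, seed=3)
        assert s.termination == "time_cap"
        assert s.duration_s == 1800.0

    def test_ri_mean_interval_matches_schedule_value(self):
        # saturating responder: realized inter-reinforcement interval has
        # mean ~ the programmed value (arming delay is exponential with
        # that mean; collection latency and frame rounding add ~1 s,
        # well inside 3 SEM at this n)
        cal = calibrate_schedule("RI", 30.0, n_rewards=1000, seed=4)
        tol = 3 * cal["sem_interval_s"]
        assert abs(cal["mean_interval_s"] - 30.0) < tol

    def test_rr_responses_per_reward_geometric(self):
        cal = calibrate_schedule("RR", 5.0, n_rewards=5000, seed=5)
        counts = cal["responses_per_reward"]
        tol = 3 * cal["sem_responses_per_reward"]
        assert abs(cal["mean_responses_per_reward"] - 5.0) < tol
        # geometric with p = 1/5: P(X = 1) = 0.2
        p1 = np.mean(counts == 1)
        assert abs(p1 - 0.2) < 3 * math.sqrt(0.2 * 0.8 / len(counts))

    @pytest.mark.parametrize("kind,value", [("RR", 5), ("RI", 30), ("FR", 3)])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_caps_never_exceeded(self, kind, value, seed):
        spec = ScheduleSpec(kind=ScheduleKind(kind), value=value,
                            session_cap_s=200.0, reward_cap=10)
        agent = AgentParams(nose_poke_rate_hz=1.5, magazine_check_rate_hz=0.1)
        s = simulate_session(spec, agent, seed=seed)
        assert s.n_rewards <= 10
        assert s.duration_s <= 200.0
        if s.termination == "reward_cap":
            assert s.n_rewards == 10

    def test_magazine_entries_and_exits_alternate(self):
        spec = ScheduleSpec(kind=ScheduleKind.RR, value=2, session_cap_s=300)
        agent = AgentParams(nose_poke_rate_hz=1.0, magazine_check_rate_hz=0.3,
                            magazine_dwell_s=3.0)
        s = simulate_session(spec, agent, seed=11)
        depth = 0
        for e in s.events:
            if e.event_type is EventType.MAGAZINE_ENTRY:
                depth += 1
                assert depth == 1
            elif e.event_type is EventType.MAGAZINE_EXIT:
                depth -= 1
                assert depth == 0

    def test_times_nonnegative_and_sorted(self):
        spec = ScheduleSpec(kind=ScheduleKind.RI, value=30, session_cap_s=300)
        agent = AgentParams(nose_poke_rate_hz=0.8, inactive_rate_hz=0.2,
                            magazine_check_rate_hz=0.2)
        s = simulate_session(spec, agent, seed=12)
        times = [e.time_s for e in s.events]
        assert all(t >= 0 for t in times)
        assert times == sorted(times)

    def test_identical_seed_identical_session(self):
        spec = ScheduleSpec(kind=ScheduleKind.RI, value=30, session_cap_s=600)
        agent = AgentParams(nose_poke_rate_hz=0.5, magazine_check_rate_hz=0.1)
        assert simulate_session(spec, agent, seed=7) == \
            simulate_session(spec, agent, seed=7)

    def test_extinction_delivers_no_rewards(self):
        spec = ScheduleSpec(kind=ScheduleKind.EXTINCTION, session_cap_s=300)
        s = simulate_session(spec, QUIET, seed=8)
        assert s.n_rewards == 0
        assert not any(e.event_type is EventType.REWARD_DELIVERY
                       for e in s.events)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ScheduleSpec(kind=ScheduleKind.RR, value=0)
        with pytest.raises(ValueError):
            ScheduleSpec(kind=ScheduleKind.RI, value=30, session_cap_s=-1)
        with pytest.raises(ValueError):
            AgentParams(nose_poke_rate_hz=-0.1)
        with pytest.raises(ValueError):
            AgentParams(devaluation_factor=1.5)
        # uncapped session with no way to terminate
        with pytest.raises(ValueError):
            simulate_session(
                ScheduleSpec(kind=ScheduleKind.RR, value=2,
                             session_cap_s=math.inf, reward_cap=None),
                QUIET, seed=0)


class TestCurriculum:
    def test_ri_track_minimum_days_progression(self):
        sessions = simulate_curriculum(
            "RI_track", AgentParams(nose_poke_rate_hz=0.0), seed=0)
        values = [s.schedule.value for s in sessions]
        assert values == [30, 30, 60, 60, 120, 120, 120, 120]

    def test_rr_track_minimum_days_endpoints(self):
        sessions = simulate_curriculum(
            "RR_track", AgentParams(nose_poke_rate_hz=0.0), seed=0)
        assert sessions[0].schedule.value == 2
        assert sessions[-1].schedule.value == 20

    def test_zero_rate_agent_times_out_everywhere(self):
        sessions = simulate_curriculum(
            "RI_track", AgentParams(nose_poke_rate_hz=0.0,
                                    inactive_rate_hz=0.0,
                                    magazine_check_rate_hz=0.0), seed=0)
        assert all(s.termination == "time_cap" and s.n_rewards == 0
                   for s in sessions)

    def test_day_counts_validated(self):
        with pytest.raises(ValueError):
            simulate_curriculum("RI_track", QUIET, days={})
        with pytest.raises(ValueError):
            simulate_curriculum("RI_track", QUIET, days={30: 5})
        with pytest.raises(ValueError):
            simulate_curriculum("sideways", QUIET)


class TestDevaluation:
    def test_habit_agent_factor_one_keeps_rate(self):
        agent = AgentParams(nose_poke_rate_hz=0.5, devaluation_factor=1.0,
                            inactive_rate_hz=0.0, magazine_check_rate_hz=0.0)
        counts = {c: len(active_pokes(simulate_devaluation_pair(
            agent, c, seed=1))) for c in ("valued", "devalued")}
        # same rate: both Poisson(300); sanity-check both are populated
        assert counts["valued"] > 200 and counts["devalued"] > 200

    def test_goal_agent_count_ratio_tracks_factor(self):
        # 200 replicate pairs at factor 0.3: mean devalued/valued ratio
        # estimates the ratio of Poisson means
        agent = AgentParams(nose_poke_rate_hz=0.5, devaluation_factor=0.3,
                            inactive_rate_hz=0.0, magazine_check_rate_hz=0.0)
        ratios = []
        for i in range(200):
            v = simulate_devaluation_pair(agent, "valued", seed=2 * i)
            d = simulate_devaluation_pair(agent, "devalued", seed=2 * i + 1)
            ratios.append(len(active_pokes(d)) / len(active_pokes(v)))
        ratios = np.asarray(ratios)
        sem = ratios.std(ddof=1) / math.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.3) < 3 * sem

    def test_zero_rate_gives_zero_pokes(self):
        agent = AgentParams(nose_poke_rate_hz=0.0, inactive_rate_hz=0.0,
                            magazine_check_rate_hz=0.0)
        for c in ("valued", "devalued"):
            assert not active_pokes(simulate_devaluation_pair(agent, c, seed=0))

    def test_sessions_are_nonreinforced(self):
        agent = AgentParams(nose_poke_rate_hz=1.0)
        s = simulate_devaluation_pair(agent, "valued", seed=3)
        assert s.n_rewards == 0 and s.duration_s == 600.0

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_devaluation_pair(QUIET, "valued", duration_s=0)
        with pytest.raises(ValueError):
            simulate_devaluation_pair(QUIET, "half-devalued")


def _one_event_session(t=5.0, duration=20.0, etype=EventType.NOSE_POKE_ACTIVE,
                       rewarded=True, label="RI"):
    return SessionRecord(
        schedule=ScheduleSpec(kind=ScheduleKind.EXTINCTION),
        events=[BehavioralEvent(t, etype, rewarded)], duration_s=duration,
        n_rewards=0, termination="time_cap", condition_label=label)


class TestTraceGenerator:
    def test_silent_generator_yields_flat_baseline(self):
        s = _one_event_session()
        p = NeuralGenParams(noise_sd=0.0, event_amplitudes={},
                            drift_slope_per_block={})
        tr = generate_trace(s, p, seed=0)
        assert np.allclose(tr.values, p.f0)

    def test_single_transient_peak_amplitude_and_lag(self):
        # peak-normalized kernel: max = f0 + a at t_event + closed-form lag
        a = 0.5
        s = _one_event_session(t=5.0)
        p = NeuralGenParams(
            noise_sd=0.0, drift_slope_per_block={},
            event_amplitudes={("RI", EventType.NOSE_POKE_ACTIVE, True): a})
        tr = generate_trace(s, p, seed=0)
        i = int(np.argmax(tr.values))
        lag = kernel_peak_lag_s(p.kernel_rise_s, p.kernel_decay_s)
        assert tr.values[i] == pytest.approx(p.f0 + a, rel=1e-3)
        assert i / p.fps == pytest.approx(5.0 + lag, abs=1.5 / p.fps)

    def test_trace_strictly_positive_under_heavy_noise(self):
        s = _one_event_session()
        p = NeuralGenParams(noise_sd=2.0)  # noise sd >> f0 forces clipping
        tr = generate_trace(s, p, seed=1)
        assert np.all(tr.values > 0)

    def test_identical_seed_identical_trace(self):
        spec = ScheduleSpec(kind=ScheduleKind.RR, value=5, session_cap_s=120)
        s = simulate_session(spec, QUIET, seed=4)
        a = generate_trace(s, NeuralGenParams(), seed=5)
        b = generate_trace(s, NeuralGenParams(), seed=5)
        assert np.array_equal(a.values, b.values)

    def test_drift_raises_amplitude_across_deciles(self):
        # 20 identical events, slope 0.1/block: last-decile transient must
        # exceed the first-decile one
        events = [BehavioralEvent(10.0 + 15.0 * i,
                                  EventType.NOSE_POKE_ACTIVE, True)
                  for i in range(20)]
        s = SessionRecord(schedule=ScheduleSpec(kind=ScheduleKind.EXTINCTION),
                          events=events, duration_s=320.0, n_rewards=0,
                          termination="time_cap", condition_label="RI")
        p = NeuralGenParams(
            noise_sd=0.0,
            event_amplitudes={("RI", EventType.NOSE_POKE_ACTIVE, True): 0.2},
            drift_slope_per_block={("RI", EventType.NOSE_POKE_ACTIVE): 0.1})
        tr = generate_trace(s, p, seed=0)
        fps = int(p.fps)
        first = tr.values[10 * fps:13 * fps].max() - p.f0
        last = tr.values[295 * fps:298 * fps].max() - p.f0
        assert first == pytest.approx(0.2, rel=1e-3)
        assert last == pytest.approx(0.2 + 9 * 0.1, rel=1e-3)

    def test_validation_errors(self):
        s = _one_event_session(duration=30.0)
        with pytest.raises(ValueError):
            NeuralGenParams(fps=30, kernel_rise_s=1.0, kernel_decay_s=0.5)
        with pytest.raises(ValueError):
            generate_trace(s, NeuralGenParams(max_duration_s=10.0))

    def test_generated_trace_passes_dff_preconditions(self):
        spec = ScheduleSpec(kind=ScheduleKind.RI, value=30, session_cap_s=120)
        s = simulate_session(spec, AgentParams(nose_poke_rate_hz=0.5), seed=6)
        tr = generate_trace(s, NeuralGenParams(), seed=7)
        dff = compute_dff(tr)  # must not raise
        assert len(dff.dff) == len(tr.values)
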