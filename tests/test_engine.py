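import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sp5c.agent import AgentAction, AgentParams, StochasticAgent, scripted_agent
from sp5c.engine import (
    TrialRecord,
    evaluate_criterion,
    run_session,
    run_trial,
    select_cue_hole,
)
from sp5c.eventlog_io import write_log
from sp5c.protocol import CriterionSpec, build_preset


def _sd1_stage(config):
    return config.stages[-1]


def _records(outcomes, stage_id=8):
    return [
        TrialRecord(trial_index=i, stage_id=stage_id, t_start=float(i),
                    outcome=o, hole=None, iti_used=5.0, sd_used=1.0,
                    correct_latency=None, magazine_latency=None,
                    in_dark_phase=True)
        for i, o in enumerate(outcomes)
    ]


# ---------------------------------------------------------------------------
# run_trial


def test_correct_trial_event_sequence(ua_config):
    stage = _sd1_stage(ua_config)
    action = AgentAction(responds=True, chosen_hole=-1, response_latency=0.8,
                         magazine_latency=1.0)
    rng = np.random.default_rng(0)
    record, events, next_avail = run_trial(stage, action, 100.0, rng, iti=5.0)
    assert record.outcome == "correct"
    kinds = [e.kind for e in events]
    assert kinds == ["trial_start", "iti_start", "stimulus_on",
                     "correct_poke", "pellet_delivered", "reward_collected"]
    assert record.correct_latency == 0.8
    # next trial earliest at reward collection + 5-s eat-interval
    assert next_avail == pytest.approx(100.0 + 5.0 + 0.8 + 1.0 + 5.0)


def test_premature_poke_ends_trial_with_5s_houselight_timeout(ua_config):
    stage = _sd1_stage(ua_config)
    action = AgentAction(premature_time=4.0, responds=True, chosen_hole=-1,
                         response_latency=0.5, magazine_latency=1.0)
    record, events, next_avail = run_trial(
        stage, action, 0.0, np.random.default_rng(0), iti=5.0)
    assert record.outcome == "premature"
    t_out = [e for e in events if e.kind == "timeout_start"]
    assert len(t_out) == 1 and t_out[0].detail["houselight"] is True
    assert next_avail == pytest.approx(4.0 + 5.0)
    assert all(e.kind != "stimulus_on" for e in events)


def test_omission_timing_sd1_limited_hold2(ua_config):
    """No response at SD 1 s + 2-s limited hold: the omission fires exactly
    3.0 s after stimulus onset, followed by a 5-s time-out."""
    stage = _sd1_stage(ua_config)
    action = AgentAction(responds=False)
    record, events, next_avail = run_trial(
        stage, action, 0.0, np.random.default_rng(0), iti=5.0)
    assert record.outcome == "omission"
    by_kind = {e.kind: e.t for e in events}
    assert by_kind["stimulus_on"] == pytest.approx(5.0)
    assert by_kind["omission"] == pytest.approx(5.0 + 1.0 + 2.0)
    assert by_kind["timeout_end"] - by_kind["timeout_start"] == pytest.approx(5.0)
    assert next_avail == pytest.approx(8.0 + 5.0)


def test_incorrect_poke_unpunished_in_single_cue_stage(ua_config):
    single_cue = ua_config.stages[2]
    assert single_cue.punish_incorrect is False
    action = AgentAction(responds=True, chosen_hole=-2, response_latency=0.7,
                         magazine_latency=1.0)
    record, events, next_avail = run_trial(
        single_cue, action, 0.0, np.random.default_rng(0), iti=5.0)
    assert record.outcome == "incorrect"
    assert all(e.kind != "timeout_start" for e in events)
    assert next_avail == pytest.approx(5.7)


def test_response_slower_than_window_counts_as_omission(ua_config):
    stage = _sd1_stage(ua_config)
    action = AgentAction(responds=True, chosen_hole=-1, response_latency=3.5,
                         magazine_latency=1.0)
    record, _, _ = run_trial(stage, action, 0.0, np.random.default_rng(0),
                             iti=5.0)
    assert record.outcome == "omission"


def test_negative_latency_rejected(ua_config):
    stage = _sd1_stage(ua_config)
    with pytest.raises(ValueError, match="negative"):
        run_trial(stage, AgentAction(responds=True, chosen_hole=-1,
                                     response_latency=-0.1,
                                     magazine_latency=1.0),
                  0.0, np.random.default_rng(0), iti=5.0)


# ---------------------------------------------------------------------------
# evaluate_criterion


def test_criterion_passes_for_50_perfect_trials():
    passed, wm = evaluate_criterion(_records(["correct"] * 50), CriterionSpec())
    assert passed
    assert wm.accuracy_pct == 100.0 and wm.omission_pct == 0.0


def test_criterion_accuracy_exactly_80_fails():
    """16/20 correct in the window is exactly 80% — the threshold is strict."""
    history = _records(["correct"] * 40 + ["correct"] * 16 + ["incorrect"] * 4)
    passed, wm = evaluate_criterion(history, CriterionSpec())
    assert wm.started_in_stage == 60
    assert wm.accuracy_pct == pytest.approx(80.0)
    assert not passed


def test_criterion_49_trials_insufficient():
    passed, _ = evaluate_criterion(_records(["correct"] * 49), CriterionSpec())
    assert not passed


def test_criterion_omission_alternative_route():
    # Window omissions >= 20% but > 200 stage-correct trials: still passes.
    history = _records(["correct"] * 210 + ["correct"] * 14 + ["omission"] * 6)
    passed, wm = evaluate_criterion(history, CriterionSpec())
    assert wm.omission_pct == pytest.approx(30.0)
    assert passed


def _brute_force_criterion(history, spec):
    window = history[-spec.window_len:] if history else []
    c = [r.outcome for r in window].count("correct")
    i = [r.outcome for r in window].count("incorrect")
    o = [r.outcome for r in window].count("omission")
    if c + i == 0:
        return False
    acc = 100.0 * c / (c + i)
    om = 100.0 * o / len(window)
    total_correct = sum(r.outcome == "correct" for r in history)
    return (len(history) >= spec.min_started and acc > spec.accuracy_gt
            and (om < spec.omission_lt or total_correct > spec.correct_alt_gt))


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(["correct", "incorrect", "omission",
                                 "premature"]), min_size=0, max_size=200),
       st.integers(0, 2 ** 31 - 1))
def test_criterion_matches_brute_force_oracle(outcomes, _salt):
    spec = CriterionSpec()
    history = _records(outcomes)
    passed, _ = evaluate_criterion(history, spec)
    assert passed == _brute_force_criterion(history, spec)


# ---------------------------------------------------------------------------
# select_cue_hole


def test_cue_holes_uniform_over_10000_draws():
    rng = np.random.default_rng(42)
    draws = [select_cue_hole(rng) for _ in range(10_000)]
    freqs = np.bincount(draws, minlength=6)[1:] / 10_000
    assert set(draws) <= {1, 2, 3, 4, 5}
    # 99% binomial interval for p=0.2, n=10,000
    assert np.all((freqs > 0.18) & (freqs < 0.22))


def test_cue_hole_sequence_deterministic_per_seed():
    rng1, rng2 = np.random.default_rng(9), np.random.default_rng(9)
    assert [select_cue_hole(rng1) for _ in range(100)] == \
        [select_cue_hole(rng2) for _ in range(100)]


def test_no_immediate_repeat_flag():
    rng = np.random.default_rng(3)
    prev = 4
    for _ in range(200):
        h = select_cue_hole(rng, [prev], no_immediate_repeat=True)
        assert h != prev
        prev = h


# ---------------------------------------------------------------------------
# run_session


def test_perfect_responder_traverses_full_ladder(perfect_training_log):
    adv = [e for e in perfect_training_log.events if e.kind == "stage_advanced"]
    assert len(adv) == 10
    # 50 trials per stage: quotas of 50 and criterion minimum of 50
    assert all(e.detail["trials_in_stage"] == 50 for e in adv)
    n_trials = sum(1 for e in perfect_training_log.events
                   if e.kind == "trial_start")
    assert n_trials == 500


def test_stage_ids_strictly_increasing(stochastic_training_log):
    ids = [e.detail["stage_id"] for e in stochastic_training_log.events
           if e.kind == "stage_advanced"]
    assert ids == sorted(ids) and len(set(ids)) == len(ids)


def test_outcome_conservation(stochastic_training_log):
    from sp5c.eventlog_io import events_to_trials
    records = [r for r in events_to_trials(stochastic_training_log)
               if not r.incomplete]
    n_starts = sum(1 for e in stochastic_training_log.events
                   if e.kind == "trial_start")
    counts = {o: sum(r.outcome == o for r in records)
              for o in ("correct", "incorrect", "omission", "premature")}
    assert sum(counts.values()) == len(records)
    assert len(records) + sum(
        1 for r in events_to_trials(stochastic_training_log) if r.incomplete
    ) == n_starts


def test_same_seed_same_log_bytes(tr_config):
    logs = [run_session(tr_config, StochasticAgent(), seed=5,
                        horizon_s=86_400.0) for _ in range(2)]
    assert write_log(logs[0]) == write_log(logs[1])


def test_zero_horizon_yields_open_close_only(tr_config):
    log = run_session(tr_config, scripted_agent("perfect"), seed=1,
                      horizon_s=0.0)
    assert [e.kind for e in log.events] == ["session_open", "session_close"]


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 20),
       p_correct=st.floats(0.2, 1.0),
       hazard=st.floats(0.0, 0.05),
       p_omit=st.floats(0.0, 0.9))
def test_tr_trials_start_only_in_access_window(tr_config, seed, p_correct,
                                               hazard, p_omit):
    """No trial starts outside the first 2.5 h of the dark phase, for any
    agent parameterization and seed."""
    params = AgentParams(p_correct=p_correct, premature_hazard=hazard,
                         p_omit_base=p_omit)
    log = run_session(tr_config, StochasticAgent(params), seed=seed,
                      horizon_s=2 * 86_400.0, max_trials=150)
    starts = [e.t for e in log.events if e.kind == "trial_start"]
    for t in starts:
        hours_into_dark = (t / 3600.0) % 24.0
        assert 0.0 <= hours_into_dark < 2.5


def test_magazine_stage_delivers_50_pellets_then_advances(ua_config):
    log = run_session(ua_config, scripted_agent("perfect"), seed=2,
                      max_trials=60)
    first_adv = next(e for e in log.events if e.kind == "stage_advanced")
    pellets_before = sum(1 for e in log.events
                         if e.kind == "pellet_delivered" and e.t <= first_adv.t)
    assert first_adv.detail["from_stage"] == 0
    assert pellets_before == 50


def test_criterion_evaluated_events_report_window_20(stochastic_training_log):
    evals = [e for e in stochastic_training_log.events
             if e.kind == "criterion_evaluated"]
    assert evals
    assert {e.detail["window_len"] for e in evals} == {20}
    assert all(e.detail["n_window"] <= 20 for e in evals)


def test_timestamps_non_decreasing(stochastic_training_log):
    ts = [e.t for e in stochastic_training_log.events]
    assert all(b >= a for a, b in zip(ts, ts[1:]))
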