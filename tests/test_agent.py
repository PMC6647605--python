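import math

import numpy as np
import pytest

from sp5c.agent import (
    AgentParams,
    DrugEffect,
    StochasticAgent,
    _sample_initiate_delay,
    decide,
    drug_magnitude,
    effective_params,
    latin_square_schedule,
    load_agent_params,
    p_omit_at_sd,
    save_agent_params,
    scripted_agent,
)
from sp5c.engine import run_session
from sp5c.eventlog_io import events_to_trials, trials_to_frame
from sp5c.metrics import accuracy, omission_pct, premature_pct
from sp5c.protocol import LightCycle, build_preset


def _sd1(config):
    return config.stages[-1]


def test_degenerate_parameters_always_correct(ua_config):
    params = AgentParams(p_correct=1.0, p_omit_base=0.0, omit_sd_slope=0.0,
                         premature_hazard=0.0)
    rng = np.random.default_rng(0)
    stage = _sd1(ua_config)
    for _ in range(50):
        a = decide(params, (), stage, 0.0, LightCycle(), rng, iti=5.0)
        assert a.responds and a.premature_time is None
        assert a.chosen_hole == -1  # relative code for the lit hole


def test_premature_probability_matches_poisson_first_event(ua_config):
    """hazard 0.05/s over a 12.5-s ITI: P(premature) = 1 - exp(-0.625)."""
    params = AgentParams(premature_hazard=0.05, p_omit_base=0.0,
                         omit_sd_slope=0.0)
    rng = np.random.default_rng(1)
    stage = _sd1(ua_config)
    n = 8000
    hits = sum(
        decide(params, (), stage, 0.0, LightCycle(), rng,
               iti=12.5).premature_time is not None
        for _ in range(n)
    )
    expected = 1.0 - math.exp(-0.625)
    se = math.sqrt(expected * (1 - expected) / n)
    assert hits / n == pytest.approx(expected, abs=4 * se)


def test_circadian_initiation_fraction_matches_rate_ratio():
    """With a 10:1 dark:light initiation-rate ratio and equal phase
    durations, the dark-phase fraction of a free-running initiation process
    approaches 10/11."""
    params = AgentParams(init_rate_dark=0.01, init_rate_light=0.001)
    lc = LightCycle()
    rng = np.random.default_rng(5)
    t, dark_hits, total = 0.0, 0, 0
    while t < 12 * 86_400.0:
        t += _sample_initiate_delay(params, t, lc.lights_off_clock, lc, rng)
        dark_hits += lc.is_dark((lc.lights_off_clock + t / 3600.0) % 24.0)
        total += 1
    frac = dark_hits / total
    expected = 10.0 / 11.0
    se = math.sqrt(expected * (1 - expected) / total)
    assert frac == pytest.approx(expected, abs=4 * se)


def test_omission_probability_rises_as_sd_shrinks():
    params = AgentParams(p_omit_base=0.15, omit_sd_slope=0.25)
    assert p_omit_at_sd(params, 1.0) == pytest.approx(0.15)
    assert p_omit_at_sd(params, 0.2) == pytest.approx(0.15 + 0.25 * 0.8)
    assert p_omit_at_sd(params, math.inf) == 0.0
    assert p_omit_at_sd(params, 16.0) == 0.0  # clamped at 0


def test_drug_kernel_halves_at_half_life():
    eff = DrugEffect(onset_t=100.0, half_life=600.0)
    assert drug_magnitude(eff, 99.9) == 0.0
    assert drug_magnitude(eff, 100.0) == 1.0
    assert drug_magnitude(eff, 700.0) == pytest.approx(0.5)
    assert drug_magnitude(eff, 1300.0) == pytest.approx(0.25)


def test_drug_effect_modulates_parameters_then_decays():
    base = AgentParams(p_correct=0.9, p_omit_base=0.1)
    eff = DrugEffect(onset_t=0.0, half_life=600.0, delta_p_correct=-0.2,
                     delta_p_omit=0.3, delta_latency_scale=1.5)
    at_peak = effective_params(base, (eff,), 0.0)
    assert at_peak.p_correct == pytest.approx(0.7)
    assert at_peak.p_omit_base == pytest.approx(0.4)
    assert at_peak.correct_latency_median == pytest.approx(
        base.correct_latency_median * 1.5)
    at_hl = effective_params(base, (eff,), 600.0)
    assert at_hl.p_correct == pytest.approx(0.8)
    assert at_hl.correct_latency_median == pytest.approx(
        base.correct_latency_median * 1.25)
    before = effective_params(base, (eff,), -1.0)
    assert before.p_correct == base.p_correct


def test_parameter_recovery_from_simulated_tr_session(tr_config):
    """Metrics computed on a ~400-trial simulated session recover the
    generative accuracy/omission/premature rates within binomial error."""
    params = AgentParams(p_correct=0.85, p_omit_base=0.18, omit_sd_slope=0.0,
                         premature_hazard=0.004)
    log = run_session(tr_config, StochasticAgent(params), seed=99,
                      initial_stage=len(tr_config.stages) - 1,
                      freeze_stage=True, horizon_s=86_400.0)
    trials = trials_to_frame([r for r in events_to_trials(log)
                              if not r.incomplete])
    n = len(trials)
    assert n > 250  # time-restricted trials/day scale

    p_prem = 1.0 - math.exp(-params.premature_hazard * 5.0)
    se = lambda p: math.sqrt(p * (1 - p) / n)
    assert premature_pct(trials) / 100 == pytest.approx(p_prem,
                                                        abs=4 * se(p_prem))
    # omissions: of non-premature trials
    p_om = params.p_omit_base * (1 - p_prem)
    assert omission_pct(trials) / 100 == pytest.approx(p_om, abs=4 * se(p_om))
    assert accuracy(trials) / 100 == pytest.approx(0.85, abs=4 * se(0.85))


# ---------------------------------------------------------------------------
# scripted agents


def test_perfect_script_all_correct(ua_config):
    log = run_session(ua_config, scripted_agent("perfect"), seed=0,
                      initial_stage=len(ua_config.stages) - 1,
                      freeze_stage=True, max_trials=30)
    outcomes = {r.outcome for r in events_to_trials(log) if not r.incomplete}
    assert outcomes == {"correct"}


def test_always_omit_script(ua_config):
    log = run_session(ua_config, scripted_agent("always_omit"), seed=0,
                      initial_stage=len(ua_config.stages) - 1,
                      freeze_stage=True, max_trials=20)
    trials = [r for r in events_to_trials(log) if not r.incomplete]
    assert omission_pct(trials) == 100.0


def test_fixed_sequence_long_run_accuracy(ua_config):
    agent = scripted_agent("fixed_sequence",
                           ["correct"] * 17 + ["incorrect"] * 3)
    log = run_session(ua_config, agent, seed=0,
                      initial_stage=len(ua_config.stages) - 1,
                      freeze_stage=True, max_trials=200)
    trials = [r for r in events_to_trials(log) if not r.incomplete]
    assert accuracy(trials) == pytest.approx(85.0)


def test_empty_fixed_sequence_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        scripted_agent("fixed_sequence", [])


# ---------------------------------------------------------------------------
# Latin square


def test_latin_square_3x3_each_dose_once_per_row_and_position():
    sched = latin_square_schedule([0, 0.1, 0.3], 3)
    for row in sched:
        assert sorted(row) == [0, 0.1, 0.3]
    for pos in range(3):
        assert sorted(row[pos] for row in sched) == [0, 0.1, 0.3]


def test_latin_square_cycled_to_12_subjects_is_position_balanced():
    sched = latin_square_schedule([0, 0.1, 0.3], 12)
    assert len(sched) == 12
    for pos in range(3):
        col = [row[pos] for row in sched]
        assert all(col.count(d) == 4 for d in (0, 0.1, 0.3))


def test_latin_square_single_subject_and_errors():
    assert sorted(latin_square_schedule([1, 2, 3], 1)[0]) == [1, 2, 3]
    with pytest.raises(ValueError):
        latin_square_schedule([1], 3)
    with pytest.raises(ValueError):
        latin_square_schedule([1, 2], 0)


def test_agent_params_file_round_trip(tmp_path):
    agents = {"r1": AgentParams(p_correct=0.8), "r2": AgentParams()}
    path = tmp_path / "agents.yaml"
    save_agent_params(agents, path)
    assert load_agent_params(path) == agents
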