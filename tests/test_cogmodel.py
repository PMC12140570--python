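"""Likelihood core: encoding, updating, softmax, fitting, CV.

``trace_loglik`` below is an independent straight-line re-trace of the model
(dict-based, naive softmax) used as the oracle for the array/kernel
implementation.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relbandit import cogmodel as cm
from relbandit.agents import simulate_session, uniform_random_params
from relbandit.cogmodel import (
    AgentParams,
    EncodingState,
    ModelSpec,
    all_model_specs,
    choice_probabilities,
    classify_feedback,
    encode_outcomes,
    fit_model,
    loo_cv,
    session_loglik,
    update_expectancies,
)


def trace_loglik(params, session):
    """Independent step-by-step trace of the three model stages."""
    trials = [t for t in session.trials if t.valid]
    q = {}
    for t in trials:
        for o in t.presented_option_ids:
            q.setdefault(o, 0.5)
    rmin = rmax = None
    ll = 0.0
    for t in trials:
        beta = params.beta_learn if t.phase == "learning" else params.beta_transfer
        order = list(t.presented_option_ids)
        us = [beta * q[o] + (params.position_bias if k == 0 else 0.0)
              for k, o in enumerate(order)]
        denom = sum(math.exp(u) for u in us)
        ll += math.log(math.exp(us[order.index(t.chosen_option_id)]) / denom)
        if t.phase == "learning":
            xs = [t.outcomes[o] for o in order]
            rmin = min(xs) if rmin is None else min(rmin, *xs)
            rmax = max(xs) if rmax is None else max(rmax, *xs)
            tmin, tmax = min(xs), max(xs)
            for o in order:
                x = t.outcomes[o]
                xa = 0.5 if rmax == rmin else (x - rmin) / (rmax - rmin)
                xr = 0.5 if tmax == tmin else (x - tmin) / (tmax - tmin)
                v = (1 - params.omega) * xa + params.omega * xr
                if o == t.chosen_option_id:
                    a = params.alpha_con if v > q[o] else params.alpha_dis
                else:
                    a = params.alpha_con if v < q[o] else params.alpha_dis
                q[o] = q[o] + a * (v - q[o])
    return ll


# -- model family ------------------------------------------------------------

def test_eight_models_and_parameter_counts():
    specs = all_model_specs()
    assert len(specs) == 8
    assert sorted(m.k for m in specs) == [3, 4, 4, 4, 5, 5, 5, 6]
    full = ModelSpec(True, 2, 2)
    assert full.k == 6 and full.name == "REL-2alpha-2beta"


def test_agent_params_constraints():
    with pytest.raises(ValueError, match="omega must be 0"):
        AgentParams(ModelSpec(False), 0.3, 0.5, 0.5, 1.0, 1.0, 0.0)
    with pytest.raises(ValueError, match="alpha_con == alpha_dis"):
        AgentParams(ModelSpec(True), 0.3, 0.5, 0.2, 1.0, 1.0, 0.0)
    with pytest.raises(ValueError, match="beta_learn == beta_transfer"):
        AgentParams(ModelSpec(True, 2, 1), 0.3, 0.5, 0.2, 1.0, 2.0, 0.0)


# -- outcome encoding ---------------------------------------------------------

def test_encode_outcomes_pure_absolute():
    v, _ = encode_outcomes([20.0, 10.0], EncodingState(0.0, 40.0), omega=0.0)
    assert v == pytest.approx([0.5, 0.25])


def test_encode_outcomes_pure_relative_two_point():
    v, _ = encode_outcomes([16.0, 14.0], EncodingState(), omega=1.0)
    assert v == pytest.approx([1.0, 0.0])


def test_encode_outcomes_hybrid():
    v, _ = encode_outcomes([20.0, 10.0], EncodingState(0.0, 40.0), omega=0.5)
    assert v[0] == pytest.approx(0.75)  # 0.5*0.5 + 0.5*1.0


def test_encode_outcomes_first_trial_extremes_map_to_unit_interval():
    """The running range absorbs the current trial before normalizing."""
    v, state = encode_outcomes([30.0, 12.0], EncodingState(), omega=0.0)
    assert v == pytest.approx([1.0, 0.0])
    assert (state.running_min, state.running_max) == (12.0, 30.0)


def test_encode_outcomes_degenerate_range():
    v, _ = encode_outcomes([5.0, 5.0], EncodingState(), omega=0.7)
    assert v == pytest.approx([0.5, 0.5])


def test_encode_outcomes_rejects_bad_omega():
    with pytest.raises(ValueError, match="omega"):
        encode_outcomes([1.0, 0.0], EncodingState(), omega=1.2)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=3),
       st.floats(0, 1))
def test_encode_outcomes_convex_combination(outcomes, omega):
    """v always lies between the absolute and relative encodings."""
    state = EncodingState(-150.0, 150.0)  # running range wider than the trial's
    x_abs, _ = encode_outcomes(outcomes, state, omega=0.0)
    x_rel, _ = encode_outcomes(outcomes, state, omega=1.0)
    v, _ = encode_outcomes(outcomes, state, omega=omega)
    lo = np.minimum(x_abs, x_rel) - 1e-12
    hi = np.maximum(x_abs, x_rel) + 1e-12
    assert np.all(v >= lo) and np.all(v <= hi)
    assert np.all(v >= -1e-12) and np.all(v <= 1 + 1e-12)


# -- feedback classification and updating ------------------------------------

@pytest.mark.parametrize("v,q,chosen,expected", [
    (0.9, 0.5, True, "confirmatory"),
    (0.2, 0.5, False, "confirmatory"),
    (0.7, 0.5, False, "disconfirmatory"),
    (0.2, 0.5, True, "disconfirmatory"),
])
def test_classify_feedback(v, q, chosen, expected):
    assert classify_feedback(v, q, chosen) == expected


def test_update_expectancies():
    q = {"a": 0.5, "b": 0.5}
    # alpha = 1 jumps straight to v
    q1 = update_expectancies(q, {"a": 0.9, "b": 0.1}, "a", 1.0, 1.0)
    assert q1 == pytest.approx({"a": 0.9, "b": 0.1})
    # confirmatory chosen outcome uses alpha_con
    q2 = update_expectancies(q, {"a": 0.9}, "a", 0.5, 0.1)
    assert q2["a"] == pytest.approx(0.7)
    assert q2["b"] == 0.5  # unpresented untouched
    # disconfirmatory unchosen outcome (better than expected) uses alpha_dis
    q3 = update_expectancies(q, {"b": 0.9}, "a", 0.5, 0.1)
    assert q3["b"] == pytest.approx(0.54)
    # alpha = 0 leaves expectancies unchanged
    q4 = update_expectancies(q, {"a": 0.9, "b": 0.1}, "a", 0.0, 0.0)
    assert q4 == q


# -- softmax choice -----------------------------------------------------------

def test_choice_probabilities_uniform_cases():
    assert choice_probabilities([0.5, 0.5], 3.0, 0.0) == pytest.approx([0.5, 0.5])
    assert choice_probabilities([0.1, 0.9, 0.4], 0.0, 0.0) == \
        pytest.approx([1 / 3] * 3)


def test_choice_probabilities_position_bias_closed_form():
    p = choice_probabilities([0.5, 0.5], 2.0, math.log(3.0))
    assert p[0] == pytest.approx(0.75)


def test_choice_probabilities_overflow_safe():
    p = choice_probabilities([7.0, -7.0], 100.0, 0.0)  # utilities +-700
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert p[0] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="beta"):
        choice_probabilities([0.5, 0.5], -1.0, 0.0)


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=3),
       st.floats(0, 50), st.floats(-5, 5))
def test_choice_probabilities_sum_to_one(q, beta, bias):
    p = choice_probabilities(q, beta, bias)
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(p >= 0)


# -- session likelihood --------------------------------------------------------

def test_session_loglik_chance_model(v2023):
    sess = simulate_session(v2023, uniform_random_params(), seed=2)
    chance = AgentParams.create(ModelSpec(False), alpha=0.5, beta=0.0,
                                position_bias=0.0)
    n = len(sess.trials)
    assert session_loglik(chance, sess) == pytest.approx(n * math.log(0.5))


def random_params(rng):
    model = ModelSpec(True, 2, 2)
    return AgentParams.create(
        model, omega=rng.uniform(), alpha=rng.uniform(),
        alpha_dis=rng.uniform(), beta=rng.uniform(0, 10),
        beta_transfer=rng.uniform(0, 10), position_bias=rng.uniform(-2, 2))


@pytest.mark.parametrize("seed", range(8))
def test_session_loglik_matches_trace_oracle(seed, v2023, bp2023):
    """Kernel likelihood equals an independent straight-line trace to 1e-10
    on randomized short sessions (binary and ternary contexts)."""
    rng = np.random.default_rng(seed)
    task = (v2023 if seed % 2 == 0 else bp2023).with_learning_trials(10)
    gen = random_params(rng)
    sess = simulate_session(task, gen, seed=seed + 100)
    sess.trials = sess.trials[:10]
    probe = random_params(rng)  # evaluate under different params than generated
    assert session_loglik(probe, sess) == pytest.approx(
        trace_loglik(probe, sess), abs=1e-10)


def test_session_loglik_invariant_to_relabeling(v2023):
    gen = AgentParams.create(ModelSpec(True), omega=0.6, alpha=0.4, beta=5.0,
                             position_bias=0.7)
    sess = simulate_session(v2023, gen, seed=3)
    rename = {oid: f"machine_{i}" for i, oid in enumerate(v2023.option_ids)}
    from dataclasses import replace
    renamed = replace(sess, trials=[
        replace(t,
                presented_option_ids=tuple(rename[o]
                                           for o in t.presented_option_ids),
                chosen_option_id=rename[t.chosen_option_id],
                outcomes=None if t.outcomes is None else
                {rename[k]: v for k, v in t.outcomes.items()})
        for t in sess.trials])
    assert session_loglik(gen, renamed) == pytest.approx(
        session_loglik(gen, sess), abs=1e-12)


def test_omega_zero_nesting_is_exact(v2023):
    """With omega = 0 the hybrid model's likelihood equals the absolute
    model's at identical remaining parameters."""
    sess = simulate_session(v2023, uniform_random_params(), seed=8)
    rel = AgentParams.create(ModelSpec(True, 2, 2), omega=0.0, alpha=0.7,
                             alpha_dis=0.2, beta=6.0, beta_transfer=3.0,
                             position_bias=1.0)
    abs_ = AgentParams.create(ModelSpec(False, 2, 2), alpha=0.7,
                              alpha_dis=0.2, beta=6.0, beta_transfer=3.0,
                              position_bias=1.0)
    assert session_loglik(rel, sess) == session_loglik(abs_, sess)


# -- fitting -------------------------------------------------------------------

def test_fit_improves_on_generating_params(v2023, rel_full, rel_full_agent):
    sessions = [simulate_session(v2023, rel_full_agent, seed=s)
                for s in range(6)]
    fit = fit_model(rel_full, sessions, n_starts=6, seed=0)
    gen_ll = sum(session_loglik(rel_full_agent, s) for s in sessions)
    assert fit.log_likelihood >= gen_ll - 1e-6
    assert fit.log_likelihood <= 0
    n = sum(len(s.trials) for s in sessions)
    assert fit.n_observations == n
    assert fit.bic == pytest.approx(rel_full.k * math.log(n)
                                    - 2 * fit.log_likelihood)


def test_fit_deterministic_given_seed(v2023, abs_simple):
    sessions = [simulate_session(v2023, uniform_random_params(), seed=s)
                for s in range(2)]
    f1 = fit_model(abs_simple, sessions, n_starts=1, seed=5)
    f2 = fit_model(abs_simple, sessions, n_starts=1, seed=5)
    assert f1.params == f2.params
    assert f1.log_likelihood == f2.log_likelihood


def test_compare_models_handles_degenerate_data(v2023):
    """All-identical choices (always the first listed) must not break
    comparison; ties in BIC break toward fewer parameters."""
    stubborn = AgentParams.create(ModelSpec(False), alpha=0.0, beta=0.0,
                                  position_bias=50.0)
    sessions = [simulate_session(v2023, stubborn, seed=s) for s in range(2)]
    results = cm.compare_models(sessions, n_starts=2, seed=0)
    assert len(results) == 8
    bics = [r.bic for r in results]
    assert bics == sorted(bics)
    for a, b in zip(results, results[1:]):
        if a.bic == b.bic:
            assert a.model.k <= b.model.k


def test_recovery_matrix_rate():
    counts = np.zeros((8, 8), dtype=int)
    counts[np.arange(8), np.arange(8)] = 3
    counts[0, 1] = 1  # one misselection
    mat = cm.RecoveryMatrix(models=all_model_specs(), counts=counts)
    assert mat.recovery_rate == pytest.approx((3 / 4 + 7) / 8)


# -- cross-validation ------------------------------------------------------------

def test_loo_cv_chance_model_pseudo_r2_zero(v2023, abs_simple):
    """Forcing beta = 0 and b = 0 makes the fitted model predict chance, so
    the out-of-sample pseudo-R^2 is exactly zero for every run."""
    sessions = [simulate_session(v2023, uniform_random_params(), seed=s)
                for s in range(3)]
    cv = loo_cv(abs_simple, sessions, n_starts=1, seed=0,
                bounds={"beta": (0.0, 0.0), "bias": (0.0, 0.0)})
    assert np.all(cv.per_run_pseudo_r2 == 0.0)
    assert cv.mean_pseudo_r2 == 0.0


def test_loo_cv_perfect_predictor_limit(v2023, abs_simple):
    """Deterministic first-listed choosers are predicted almost perfectly by
    a large fitted position bias: pseudo-R^2 approaches 1 and never exceeds it."""
    stubborn = AgentParams.create(ModelSpec(False), alpha=0.0, beta=0.0,
                                  position_bias=50.0)
    sessions = [simulate_session(v2023, stubborn, seed=s) for s in range(3)]
    cv = loo_cv(abs_simple, sessions, n_starts=3, seed=1,
                bounds={"bias": (-50.0, 50.0)})
    assert np.all(cv.per_run_pseudo_r2 <= 1.0)
    assert cv.mean_pseudo_r2 > 0.95
    with pytest.raises(ValueError, match="at least 2 runs"):
        loo_cv(abs_simple, sessions[:1])
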