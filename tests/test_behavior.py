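"""Single-prey optimal behavior: rate algebra, regimes, exact optimality."""

import math

import numpy as np
import pytest

from obmlake.behavior import (
    FeedingEnvironment,
    Regime,
    TradeoffParams,
    emergent_functional_response,
    feeding_activity,
    feeding_level,
    fitness,
    ingestion,
    optimal_p,
    smooth_predation,
    total_metabolism,
    total_mortality,
)

from conftest import draw_environment, draw_tradeoff, grid_oracle_max


def env_with(**kw) -> FeedingEnvironment:
    base = dict(R=1.0, c=1.0, f_gut=1.0, f_veg=1.0, i_max=1.0, a=1.0,
                u=0.0, m_nat=1e-3, m_pred_s=0.0)
    base.update(kw)
    return FeedingEnvironment(**base)


@pytest.mark.parametrize(
    "p, f_fc, expected",
    [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (0.5, 0.675, 0.6625)],
)
def test_feeding_activity_linear_tradeoff(p, f_fc, expected):
    assert feeding_activity(p, f_fc) == pytest.approx(expected, abs=1e-15)


@pytest.mark.parametrize("bad", [(-0.1, 0.5), (1.1, 0.5), (0.5, -0.1), (0.5, 1.5)])
def test_feeding_activity_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        feeding_activity(*bad)


@pytest.mark.parametrize(
    "env_kw, f_feed, expected",
    [
        (dict(R=0.0), 1.0, 0.0),                       # nothing encountered
        (dict(R=1.0, c=1.0, f_gut=1.0, i_max=1.0), 1.0, 0.5),  # half-saturation
        (dict(R=9.0, c=1.0, f_gut=1.0, i_max=1.0), 1.0, 0.9),
    ],
)
def test_feeding_level_saturation(env_kw, f_feed, expected):
    assert feeding_level(env_with(**env_kw), f_feed) == pytest.approx(expected)


def test_feeding_level_degenerate_capacity():
    with pytest.raises(ValueError):
        feeding_level(env_with(i_max=0.0), 1.0)


def test_ingestion_examples():
    assert ingestion(env_with(R=0.0), 1.0) == 0.0
    # encounter at half saturation, perfect assimilation: g = 1 * (1 - 1/2)
    assert ingestion(env_with(), 1.0) == pytest.approx(0.5)


def test_ingestion_reduces_to_holling_type_ii(rng):
    """At full feeding activity the gut-limited form is a type II response."""
    for _ in range(300):
        env = draw_environment(rng)
        g = ingestion(env, 1.0)
        holling = (env.a * env.c * env.f_veg * env.R * env.i_max
                   / (env.i_max + env.c * env.f_veg * env.f_gut * env.R))
        assert g == pytest.approx(holling, rel=1e-12)


@pytest.mark.parametrize(
    "p, f_pm, m_nat, m_pred_s, expected",
    [
        (1.0, 1.0, 0.001, 0.5, 0.001),
        (0.0, 1.0, 0.001, 0.5, 0.501),
        (0.5, 0.9, 0.0, 1.0, 0.55),
    ],
)
def test_total_mortality_mitigation(p, f_pm, m_nat, m_pred_s, expected):
    assert total_mortality(p, f_pm, m_nat, m_pred_s) == pytest.approx(expected)


def test_smoothing_filter_fixed_point_and_relaxation():
    assert smooth_predation(0.37, 0.37) == pytest.approx(0.37, abs=1e-15)
    assert smooth_predation(0.0, 1.25) == pytest.approx(0.25)
    # constant forcing from zero: geometric approach with factor 0.8 per step
    m = 0.0
    for n in range(1, 60):
        m = smooth_predation(m, 1.0)
        assert m == pytest.approx(1.0 - 0.8**n, rel=1e-12)


@pytest.mark.parametrize(
    "u, f_rf, f_feed, expected",
    [(0.02, 0.7, 0.0, 0.02), (0.02, 0.0, 1.0, 0.02), (0.01, 0.5, 1.0, 0.015)],
)
def test_total_metabolism(u, f_rf, f_feed, expected):
    assert total_metabolism(u, f_rf, f_feed) == pytest.approx(expected)


def test_fitness_ratio_arithmetic():
    # net gain 0.01 at p=0, mortality m_nat=0.001, no predation: W = 10
    env = env_with(R=1.0, c=0.04, f_gut=0.0, i_max=1.0, a=1.0, u=0.03,
                   m_nat=0.001, m_pred_s=0.0)
    # f_gut=0 keeps F=0 so g = c*R = 0.04; u_tot = 0.03 -> net 0.01
    W, regime = fitness(0.0, env, TradeoffParams(1.0, 1.0, 0.0))
    assert regime is Regime.NORMAL
    assert W == pytest.approx(10.0)


def test_fitness_starvation_returns_basal_loss():
    env = env_with(R=1e-9, c=1.0, u=0.02, m_pred_s=0.1)
    tp = TradeoffParams(1.0, 1.0, 0.5)
    for p in (0.0, 0.3, 1.0):
        W, regime = fitness(p, env, tp)
        assert regime is Regime.STARVATION_STOP
        assert W == pytest.approx(-env.u)


def test_optimal_p_no_risk_no_cost_saving_feeds_fully():
    env = env_with(R=10.0, c=1.0, u=0.01, m_pred_s=0.0)
    sol = optimal_p(env, TradeoffParams(f_pm=1.0, f_fc=1.0, f_rf=0.0))
    assert sol.regime is Regime.NORMAL
    # W is maximal (flat or peaked) at full feeding; any mitigation only
    # reduces intake -- but the largest-p tie-break applies on flat W
    assert sol.fitness >= grid_oracle_max(env, TradeoffParams(1.0, 1.0, 0.0)) - 1e-12


def test_optimal_p_stop_branch_rates():
    env = env_with(R=1e-9, c=1.0, u=0.02, m_nat=0.001, m_pred_s=0.4)
    sol = optimal_p(env, TradeoffParams(f_pm=0.75, f_fc=1.0, f_rf=0.5))
    assert sol.regime is Regime.STARVATION_STOP
    assert sol.p_star == 1.0 and sol.f_feed == 0.0 and sol.g == 0.0
    assert sol.m_tot == pytest.approx(0.001 + 0.25 * 0.4)
    assert sol.u_tot == pytest.approx(env.u)


def test_optimal_p_starvation_feed_branch():
    # net gain at full feeding slightly negative but above -u: keep feeding
    env = env_with(R=0.02, c=1.0, f_gut=1.0, i_max=1.0, a=0.5, u=0.02,
                   m_nat=0.001, m_pred_s=0.3)
    tp = TradeoffParams(1.0, 1.0, 0.2)
    g_pot = ingestion(env, 1.0)
    assert -env.u < g_pot - total_metabolism(env.u, tp.f_rf, 1.0) < 0
    sol = optimal_p(env, tp)
    assert sol.regime is Regime.STARVATION_FEED
    assert sol.p_star == 0.0 and sol.f_feed == 1.0


def test_starvation_branch_never_fitness_decreasing(rng):
    """Near the shutdown threshold the chosen branch beats the alternative."""
    tp = TradeoffParams(1.0, 1.0, 0.5)
    for _ in range(200):
        u = 10 ** rng.uniform(-3, -1)
        # availability straddling the threshold g_pot = f_rf * u
        R_thresh = tp.f_rf * u  # a=1, F ~ 0 at tiny R with c=1, i_max=1
        env = env_with(R=R_thresh * 10 ** rng.uniform(-0.3, 0.3), c=1.0,
                       u=u, m_nat=1e-3, m_pred_s=10 ** rng.uniform(-3, -1))
        sol = optimal_p(env, tp)
        w_feed = ingestion(env, 1.0) - total_metabolism(u, tp.f_rf, 1.0)
        w_stop = -u
        if sol.regime is Regime.STARVATION_STOP:
            assert w_stop >= w_feed - 1e-12
        elif sol.regime is Regime.STARVATION_FEED:
            assert w_feed >= w_stop - 1e-12


def test_optimal_p_matches_grid_oracle(rng):
    """Closed-form solution attains the global fitness maximum (200 draws)."""
    checked = 0
    while checked < 200:
        env = draw_environment(rng)
        tp = draw_tradeoff(rng)
        sol = optimal_p(env, tp)
        if sol.regime is not Regime.NORMAL:
            continue
        W_ref = grid_oracle_max(env, tp)
        assert sol.fitness >= W_ref - 1e-6 * max(abs(W_ref), 1e-300)
        checked += 1


def test_p_star_monotone_in_predation_risk():
    """With the full trade-off, more ambient risk never lowers mitigation."""
    tp = TradeoffParams(1.0, 1.0, 0.5)
    for R in (0.5, 1.0, 3.0):
        prev_p = -1.0
        prev_cons = np.inf
        for m in np.logspace(-4, -0.5, 12):
            env = env_with(R=R, c=1.0, i_max=1.0, a=0.7, u=0.01,
                           m_nat=1e-3, m_pred_s=float(m))
            sol = optimal_p(env, tp)
            assert sol.p_star >= prev_p - 1e-9
            cons = sol.g / env.a
            assert cons <= prev_cons + 1e-9
            prev_p, prev_cons = sol.p_star, cons


def test_solution_invariants(rng):
    for _ in range(200):
        tp = draw_tradeoff(rng)
        sol = optimal_p(draw_environment(rng), tp)
        assert 0.0 <= sol.p_star <= 1.0
        assert 0.0 <= sol.f_feed <= 1.0
        assert sol.g >= 0.0 and sol.u_tot >= 0.0 and sol.m_tot >= 0.0
        assert 0.0 <= sol.feeding_level < 1.0
        if sol.regime is Regime.STARVATION_STOP:
            assert sol.f_feed == 0.0 and sol.p_star == 1.0
        elif sol.regime is Regime.STARVATION_FEED:
            assert sol.p_star == 0.0
        else:
            assert sol.f_feed == pytest.approx(1.0 - sol.p_star * tp.f_fc)


def test_functional_response_risk_ordering():
    """Higher ambient risk lowers the whole emergent response curve."""
    tp = TradeoffParams(f_pm=1.0, f_fc=1.0, f_rf=0.5)
    base = env_with(R=1.0, c=1.0, i_max=1.0, a=0.7, u=0.01, m_nat=1e-3)
    R = np.linspace(1e-3, 3.0, 150)
    lo = emergent_functional_response(env_with(R=1, c=1, i_max=1, a=0.7, u=0.01,
                                               m_nat=1e-3, m_pred_s=0.001), tp, R)
    hi = emergent_functional_response(env_with(R=1, c=1, i_max=1, a=0.7, u=0.01,
                                               m_nat=1e-3, m_pred_s=0.01), tp, R)
    assert np.all(hi["scaled_consumption"].values
                  <= lo["scaled_consumption"].values + 1e-12)
    stopped = hi[hi["regime"] == "starvation_stop"]
    assert (stopped["scaled_consumption"] == 0).all()


def test_functional_response_nonmonotone_at_submaximal_cost():
    """At f_FC < 1 and high risk, consumption dips at intermediate food."""
    tp = TradeoffParams(f_pm=1.0, f_fc=0.9, f_rf=0.5)
    env = env_with(R=1, c=1, i_max=1, a=0.7, u=0.01, m_nat=1e-3, m_pred_s=0.01)
    df = emergent_functional_response(env, tp, np.linspace(1e-3, 3.0, 300))
    assert np.any(np.diff(df["scaled_consumption"].values) < -1e-9)
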