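"""Multi-prey feeding: diet breadth, mode allocation, aggregate collapse."""

import itertools

import numpy as np
import pytest

from obmlake.behavior import FeedingEnvironment, Regime, TradeoffParams, optimal_p
from obmlake.diet import (
    PreyItem,
    aggregate_feeding_level,
    allocate_modes,
    diet_then_behavior,
    optimal_diet,
)
from obmlake.diet import _diet_assimilation


def test_aggregate_feeding_level_reduces_to_single_prey():
    prey = [PreyItem("z", R=2.0, c=0.5, f_gut=1.5, a=0.7)]
    env = FeedingEnvironment(R=2.0, c=0.5, f_gut=1.5, i_max=0.4)
    from obmlake.behavior import feeding_level

    assert aggregate_feeding_level(prey, 0.4, 0.8) == pytest.approx(
        feeding_level(env, 0.8)
    )


def test_aggregate_feeding_level_split_prey_equivalence():
    one = [PreyItem("a", R=2.0, c=0.5, f_gut=1.0, a=0.7)]
    two = [
        PreyItem("a1", R=1.0, c=0.5, f_gut=1.0, a=0.7),
        PreyItem("a2", R=1.0, c=0.5, f_gut=1.0, a=0.7),
    ]
    assert aggregate_feeding_level(two, 0.3) == pytest.approx(
        aggregate_feeding_level(one, 0.3)
    )
    assert aggregate_feeding_level([], 0.3) == 0.0


def test_optimal_diet_single_and_low_quality_exclusion():
    good = PreyItem("good", R=5.0, c=1.0, f_gut=1.0, a=0.9)
    ballast = PreyItem("ballast", R=50.0, c=1.0, f_gut=500.0, a=0.1)
    assert optimal_diet([good], 0.5) == [good]
    chosen = optimal_diet([good, ballast], 0.5)
    assert [p.id for p in chosen] == ["good"]


def test_optimal_diet_zero_gut_cost_always_included():
    free = PreyItem("free", R=0.01, c=0.1, f_gut=0.0, a=0.2)
    other = PreyItem("other", R=5.0, c=1.0, f_gut=1.0, a=0.9)
    assert {p.id for p in optimal_diet([free, other], 0.5)} >= {"free"}


def test_optimal_diet_matches_exhaustive_search(rng):
    """Greedy profitability ranking equals brute force over all subsets."""
    for _ in range(500):
        n = rng.integers(1, 6)
        prey = [
            PreyItem(
                f"p{i}",
                R=10 ** rng.uniform(-2, 1),
                c=10 ** rng.uniform(-2, 1),
                f_gut=10 ** rng.uniform(-1, 1.5),
                a=rng.uniform(0.05, 1.0),
            )
            for i in range(n)
        ]
        i_max = 10 ** rng.uniform(-2, 0.5)
        greedy = _diet_assimilation(optimal_diet(prey, i_max), i_max, 1.0)
        best = max(
            _diet_assimilation(list(s), i_max, 1.0)
            for k in range(1, n + 1)
            for s in itertools.combinations(prey, k)
        )
        assert greedy == pytest.approx(best, rel=1e-12, abs=1e-300)


@pytest.mark.parametrize(
    "rates, expected",
    [
        ({"pelagic": 0.02}, {"pelagic": 1.0}),
        ({"pelagic": 0.02, "benthic": 0.01}, {"pelagic": 2 / 3, "benthic": 1 / 3}),
        ({"pelagic": 0.0, "benthic": 0.0}, {"pelagic": 0.5, "benthic": 0.5}),
    ],
)
def test_allocate_modes(rates, expected):
    w = allocate_modes(rates)
    assert w == pytest.approx(expected)
    assert sum(w.values()) == pytest.approx(1.0)


def test_diet_then_behavior_single_prey_reduction():
    """One prey, one mode: identical to the single-prey behavior solution."""
    prey = [PreyItem("zoo", R=0.8, c=0.5, f_gut=1.2, a=0.7, mode="pelagic")]
    diet, beh = diet_then_behavior(
        prey, i_max=0.1, u=0.01, m_nat=0.002, m_pred_s=0.02,
        tp=TradeoffParams(1.0, 1.0, 0.5),
    )
    env = FeedingEnvironment(R=0.8, c=0.5, f_gut=1.2, i_max=0.1, a=0.7,
                             u=0.01, m_nat=0.002, m_pred_s=0.02)
    ref = optimal_p(env, TradeoffParams(1.0, 1.0, 0.5))
    assert beh.p_star == pytest.approx(ref.p_star, abs=1e-12)
    assert beh.g == pytest.approx(ref.g, rel=1e-12)
    assert beh.fitness == pytest.approx(ref.fitness, rel=1e-12)
    assert diet.mode_weights == {"pelagic": 1.0}


def test_diet_then_behavior_empty_mode_gets_no_weight():
    prey = [
        PreyItem("zoo", R=0.8, c=0.5, f_gut=1.0, a=0.7, mode="pelagic"),
        PreyItem("dust", R=0.0, c=0.5, f_gut=1.0, a=0.7, mode="benthic"),
    ]
    diet, _ = diet_then_behavior(
        prey, i_max=0.1, u=0.01, m_nat=0.002, m_pred_s=0.0,
        tp=TradeoffParams(1.0, 1.0, 0.5),
    )
    assert diet.mode_weights["pelagic"] == pytest.approx(1.0)
    assert diet.mode_weights["benthic"] == pytest.approx(0.0)


def test_diet_then_behavior_mass_consistency(rng):
    """Per-prey assimilation sums to the behavioral solution's g; feeding
    never assimilates more than the full-feeding potential."""
    for _ in range(200):
        n = rng.integers(1, 5)
        modes = ["pelagic", "benthic", "piscivorous"]
        prey = [
            PreyItem(
                f"p{i}",
                R=10 ** rng.uniform(-2, 1),
                c=10 ** rng.uniform(-2, 1),
                f_gut=10 ** rng.uniform(-1, 1),
                a=rng.uniform(0.1, 1.0),
                mode=modes[rng.integers(0, 3)],
            )
            for i in range(n)
        ]
        diet, beh = diet_then_behavior(
            prey,
            i_max=10 ** rng.uniform(-2, 0.5),
            u=10 ** rng.uniform(-4, -1),
            m_nat=10 ** rng.uniform(-4, -2),
            m_pred_s=10 ** rng.uniform(-4, -1),
            tp=TradeoffParams(rng.uniform(0.1, 1), rng.uniform(0.1, 1), 0.5),
        )
        assert sum(diet.per_prey_ingestion.values()) == pytest.approx(beh.g, rel=1e-9, abs=1e-15)
        assert beh.g <= diet.g_pot_agg + 1e-12
        assert sum(diet.mode_weights.values()) == pytest.approx(1.0)
        for pid, assim in diet.per_prey_ingestion.items():
            assert 0.0 <= assim <= diet.per_prey_capture[pid] + 1e-15


def test_diet_then_behavior_no_food_stops_feeding():
    prey = [PreyItem("zoo", R=0.0, c=0.5, f_gut=1.0, a=0.7, mode="pelagic")]
    _, beh = diet_then_behavior(
        prey, i_max=0.1, u=0.01, m_nat=0.002, m_pred_s=0.1,
        tp=TradeoffParams(1.0, 1.0, 0.5),
    )
    assert beh.regime is Regime.STARVATION_STOP
    assert beh.g == 0.0
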