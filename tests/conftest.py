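"""Shared fixtures: random parameter draws and small scenario configs."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from obmlake.behavior import FeedingEnvironment, TradeoffParams
from obmlake.fixtures import baseline_config
from obmlake.forcing import ChannelParams


def draw_environment(rng: np.random.Generator) -> FeedingEnvironment:
    """A plausible random feeding environment (rates log-uniform)."""
    return FeedingEnvironment(
        R=10 ** rng.uniform(-3, 2),
        c=10 ** rng.uniform(-3, 1),
        f_gut=10 ** rng.uniform(-1, 1),
        f_veg=rng.uniform(0.2, 1.0),
        i_max=10 ** rng.uniform(-2, 0.5),
        a=rng.uniform(0.3, 1.0),
        u=10 ** rng.uniform(-4, -1),
        m_nat=10 ** rng.uniform(-4, -2),
        m_pred_s=10 ** rng.uniform(-4, -0.5),
    )


def draw_tradeoff(rng: np.random.Generator) -> TradeoffParams:
    return TradeoffParams(
        f_pm=rng.uniform(0.01, 1.0),
        f_fc=rng.uniform(0.01, 1.0),
        f_rf=10 ** rng.uniform(-2, 0.5),
    )


def grid_oracle_max(env: FeedingEnvironment, tp: TradeoffParams, n: int = 10_001):
    """Independent maximizer of the Gilliam ratio: dense grid + local refine.

    Evaluates the fitness ratio directly from its defining rates (vectorized,
    no shared code path with the production solver) on an ``n``-point grid
    over [0, 1], then golden-sections the bracketing interval.
    """
    from scipy.optimize import minimize_scalar

    p = np.linspace(0.0, 1.0, n)
    f_feed = 1.0 - p * tp.f_fc
    load = f_feed * env.f_veg * env.c * env.f_gut * env.R
    F = np.where(load > 0, load / (env.i_max + load), 0.0)
    g = env.a * f_feed * env.f_veg * env.c * env.R * (1.0 - F)
    u_tot = (1.0 + tp.f_rf * f_feed) * env.u
    m_tot = env.m_nat + (1.0 - p * tp.f_pm) * env.m_pred_s
    W = (g - u_tot) / m_tot
    k = int(W.argmax())

    def neg(pp: float) -> float:
        ff = 1.0 - pp * tp.f_fc
        ld = ff * env.f_veg * env.c * env.f_gut * env.R
        FF = ld / (env.i_max + ld) if ld > 0 else 0.0
        gg = env.a * ff * env.f_veg * env.c * env.R * (1.0 - FF)
        return -((gg - (1.0 + tp.f_rf * ff) * env.u)
                 / (env.m_nat + (1.0 - pp * tp.f_pm) * env.m_pred_s))

    lo, hi = p[max(k - 1, 0)], p[min(k + 1, n - 1)]
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-14})
    return max(float(W[k]), -float(res.fun))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240807)


@pytest.fixture(scope="session")
def closed_config():
    """Baseline calibration with load and flush zeroed: a closed system."""
    cfg = baseline_config(obm=True)
    return replace(
        cfg,
        lower=replace(cfg.lower, flush=0.0),
        forcing=replace(cfg.forcing, load=ChannelParams(mean=0.0)),
    )
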