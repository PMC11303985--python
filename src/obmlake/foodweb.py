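"""Minimal 0-D lake food-web simulator with optimal fish behavior.

Seven pools in a single mass currency (nutrient-equivalent biomass,
g m^-3, all column-averaged): dissolved nutrient, phytoplankton,
zooplankton, zoobenthos, sediment particulate organic matter (POM),
omnivorous fish and predator fish.  The lower food web is a conventional
seasonally forced closure (Monod nutrient uptake for phytoplankton scaled
by light and temperature, Holling type II grazing for zooplankton and
zoobenthos).  The two fish groups feed through the multi-prey optimal
behavior machinery: omnivorous fish on zooplankton (pelagic mode),
zoobenthos and sediment POM (benthic mode), predator fish on omnivorous
fish (piscivorous mode).

Integration is forward Euler at a daily step, matching the daily cadence of
the behavioral decision and of the predation-risk smoother.  Every
ingestion term appears as a loss on its prey pool; unassimilated ingestion
and mortality route to sediment POM; POM mineralizes back to dissolved
nutrient.  External nutrient load is the only input and an optional flush
on the dissolved and phytoplankton pools the only output, so with both at
zero the system is closed and total mass is conserved to round-off.

The predator experiences no predation itself, so its behavior reduces to
optimizing net energy gain (its mitigation parameters do not affect any
mortality).  The predation risk omnivorous fish respond to is the smoothed
per-capita capture rate of the predator population; the biomass fraction
``p* * f_PM`` of the omnivores is unavailable to the predator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .behavior import Regime, TradeoffParams, smooth_predation
from .diet import PreyItem, diet_then_behavior
from .forcing import DAYS_PER_YEAR, ForcingParams, ForcingSample, annual_table
from .stats import ScenarioResult

__all__ = [
    "PreySpec",
    "GroupConfig",
    "LowerWebConfig",
    "LakeConfig",
    "FoodWebState",
    "step",
    "run",
]

POOLS = (
    "nutrient",
    "phytoplankton",
    "zooplankton",
    "zoobenthos",
    "sediment_pom",
    "omnivore",
    "predator",
)

T_REF = 20.0  # degC reference for Q10 scaling


def q10_scale(temperature: float, q10: float) -> float:
    """Exponential temperature scaling rate(T) = rate_ref * Q10**((T-Tref)/10)."""
    return q10 ** ((temperature - T_REF) / 10.0)


@dataclass(frozen=True)
class PreySpec:
    """One entry of a fish group's prey menu, pointing at a state pool."""

    pool: str
    mode: str
    c: float       # clearance rate, m^3 g^-1 d^-1
    f_gut: float   # gut occupation factor
    a: float       # assimilation efficiency


@dataclass(frozen=True)
class GroupConfig:
    """Rate parameters, trade-off and prey menu for one fish group."""

    name: str
    i_max_ref: float          # max gut-limited consumption at T_REF, d^-1
    u_ref: float              # basal metabolic rate at T_REF, d^-1
    m_nat: float              # background natural mortality, d^-1
    q10: float
    tradeoff: TradeoffParams
    obm: bool
    prey: tuple[PreySpec, ...]
    f_veg: float = 1.0

    def __post_init__(self) -> None:
        if self.m_nat <= 0.0:
            raise ValueError(f"group {self.name!r}: m_nat must be > 0")
        for v in (self.i_max_ref, self.u_ref, self.q10):
            if v <= 0.0:
                raise ValueError(f"group {self.name!r}: rates and q10 must be > 0")


@dataclass(frozen=True)
class LowerWebConfig:
    """Plankton/benthos closure and recycling rates (module-owned, at T_REF)."""

    phyto_mu_max: float = 1.2      # d^-1
    phyto_k_n: float = 0.10        # g m^-3 half-saturation
    phyto_resp: float = 0.06       # d^-1, to nutrient
    phyto_loss: float = 0.04       # d^-1, sinking/mortality to POM
    phyto_q10: float = 1.9
    zoo_i_max: float = 0.60        # d^-1
    zoo_k: float = 0.50            # g m^-3
    zoo_a: float = 0.70
    zoo_resp: float = 0.08         # d^-1
    zoo_mort: float = 0.03         # d^-1, to POM
    zoo_q10: float = 2.2
    benthos_i_max: float = 0.10    # d^-1
    benthos_k: float = 3.0         # g m^-3 POM
    benthos_a: float = 0.50
    benthos_resp: float = 0.01     # d^-1
    benthos_mort: float = 0.01     # d^-1
    benthos_q10: float = 2.0
    mineralization: float = 0.01   # d^-1, POM -> nutrient
    mineralization_q10: float = 2.0
    flush: float = 0.0             # d^-1 outflow on nutrient + phytoplankton


@dataclass(frozen=True)
class LakeConfig:
    """Complete scenario definition."""

    lower: LowerWebConfig = field(default_factory=LowerWebConfig)
    omnivore: GroupConfig = None  # type: ignore[assignment]
    predator: GroupConfig = None  # type: ignore[assignment]
    forcing: ForcingParams = field(default_factory=ForcingParams)
    load_scale: float = 1.0
    chlorophyll_per_biomass: float = 10.0  # proxy units per g m^-3
    initial: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.omnivore is None or self.predator is None:
            raise ValueError("both fish groups must be configured")


@dataclass
class FoodWebState:
    """Pools (g m^-3) and behavioral memory at one instant."""

    pools: dict[str, float]
    m_pred_s: float = 0.0   # smoothed predation risk seen by omnivorous fish
    time: float = 0.0       # days since start

    def __post_init__(self) -> None:
        missing = set(POOLS) - set(self.pools)
        if missing:
            raise ValueError(f"missing pools: {sorted(missing)}")
        for k, v in self.pools.items():
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"pool {k!r} must be finite and >= 0, got {v}")

    def total_mass(self) -> float:
        return float(sum(self.pools.values()))


DEFAULT_INITIAL = {
    "nutrient": 0.8,
    "phytoplankton": 0.5,
    "zooplankton": 0.3,
    "zoobenthos": 1.0,
    "sediment_pom": 8.0,
    "omnivore": 1.0,
    "predator": 0.3,
}

#: pool floor keeping populations revivable after washout (g m^-3)
POOL_FLOOR = 1e-12


class _Fluxes:
    """Source-minus-sink bookkeeping with guaranteed pairwise conservation."""

    def __init__(self, pools: dict[str, float]) -> None:
        self.pools = pools
        self.delta = {k: 0.0 for k in pools}
        self.export = 0.0
        self.imports = 0.0

    def transfer(self, src: str | None, dst: str | None, rate: float) -> None:
        """Move ``rate`` (g m^-3 d^-1) from ``src`` to ``dst`` (None = outside)."""
        if rate == 0.0:
            return
        if src is not None:
            self.delta[src] -= rate
        else:
            self.imports += rate
        if dst is not None:
            self.delta[dst] += rate
        else:
            self.export += rate


def _fish_feeding(
    cfg: GroupConfig,
    availability: dict[str, float],
    fT: float,
    m_pred_s: float,
):
    """Diet + behavior for one fish group at the current temperature."""
    prey = [
        PreyItem(id=ps.pool, R=availability[ps.pool], c=ps.c, f_gut=ps.f_gut,
                 a=ps.a, mode=ps.mode)
        for ps in cfg.prey
    ]
    return diet_then_behavior(
        prey,
        i_max=cfg.i_max_ref * fT,
        u=cfg.u_ref * fT,
        m_nat=cfg.m_nat,
        m_pred_s=m_pred_s,
        tp=cfg.tradeoff,
        f_veg=cfg.f_veg,
        p_fixed=None if cfg.obm else 0.0,
    )


def step(
    state: FoodWebState,
    forcing: ForcingSample,
    cfg: LakeConfig,
    dt: float = 1.0,
) -> tuple[FoodWebState, dict]:
    """Advance the food web one explicit-Euler step of ``dt`` days.

    Returns the new state and a diagnostics dict (behavioral solutions,
    clipping ledger, external input/export masses for the step).
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    P = state.pools
    lw = cfg.lower
    T = forcing.temperature
    fx = _Fluxes(P)

    # --- lower food web -------------------------------------------------
    fT_p = q10_scale(T, lw.phyto_q10)
    growth = (
        lw.phyto_mu_max * fT_p * forcing.light_factor
        * P["nutrient"] / (P["nutrient"] + lw.phyto_k_n)
        * P["phytoplankton"]
        if P["nutrient"] > 0.0
        else 0.0
    )
    fx.transfer("nutrient", "phytoplankton", growth)
    fx.transfer("phytoplankton", "nutrient", lw.phyto_resp * fT_p * P["phytoplankton"])
    fx.transfer("phytoplankton", "sediment_pom", lw.phyto_loss * P["phytoplankton"])

    fT_z = q10_scale(T, lw.zoo_q10)
    graze = (
        lw.zoo_i_max * fT_z * P["phytoplankton"] / (P["phytoplankton"] + lw.zoo_k)
        * P["zooplankton"]
        if P["phytoplankton"] > 0.0
        else 0.0
    )
    fx.transfer("phytoplankton", "zooplankton", lw.zoo_a * graze)
    fx.transfer("phytoplankton", "sediment_pom", (1.0 - lw.zoo_a) * graze)
    fx.transfer("zooplankton", "nutrient", lw.zoo_resp * fT_z * P["zooplankton"])
    fx.transfer("zooplankton", "sediment_pom", lw.zoo_mort * P["zooplankton"])

    fT_b = q10_scale(T, lw.benthos_q10)
    bfeed = (
        lw.benthos_i_max * fT_b * P["sediment_pom"] / (P["sediment_pom"] + lw.benthos_k)
        * P["zoobenthos"]
        if P["sediment_pom"] > 0.0
        else 0.0
    )
    fx.transfer("sediment_pom", "zoobenthos", lw.benthos_a * bfeed)
    # unassimilated benthic ingestion stays in the sediment pool
    fx.transfer("zoobenthos", "nutrient", lw.benthos_resp * fT_b * P["zoobenthos"])
    fx.transfer("zoobenthos", "sediment_pom", lw.benthos_mort * P["zoobenthos"])

    fx.transfer("sediment_pom", "nutrient",
                lw.mineralization * q10_scale(T, lw.mineralization_q10) * P["sediment_pom"])

    # --- omnivorous fish -------------------------------------------------
    om = cfg.omnivore
    fT_om = q10_scale(T, om.q10)
    avail = {ps.pool: P[ps.pool] for ps in om.prey}
    om_diet, om_beh = _fish_feeding(om, avail, fT_om, state.m_pred_s)
    B_om = P["omnivore"]
    for pool, capture in om_diet.per_prey_capture.items():
        caught = capture * B_om                      # g m^-3 d^-1 removed from prey
        assim = om_diet.per_prey_ingestion[pool] * B_om
        fx.transfer(pool, "omnivore", caught)
        fx.transfer("omnivore", "sediment_pom", caught - assim)
    fx.transfer("omnivore", "nutrient", om_beh.u_tot * B_om)
    fx.transfer("omnivore", "sediment_pom", om.m_nat * B_om)

    # --- predator fish ----------------------------------------------------
    pr = cfg.predator
    fT_pr = q10_scale(T, pr.q10)
    vulnerable = (1.0 - om_beh.p_star * om.tradeoff.f_pm) * B_om
    pr_avail = {ps.pool: vulnerable for ps in pr.prey}
    # top predator: no predation risk, behavior is pure energetics
    pr_diet, pr_beh = _fish_feeding(pr, pr_avail, fT_pr, 0.0)
    B_pr = P["predator"]
    for pool, capture in pr_diet.per_prey_capture.items():
        caught = capture * B_pr
        assim = pr_diet.per_prey_ingestion[pool] * B_pr
        fx.transfer(pool, "predator", caught)
        fx.transfer("predator", "sediment_pom", caught - assim)
    fx.transfer("predator", "nutrient", pr_beh.u_tot * B_pr)
    fx.transfer("predator", "sediment_pom", pr.m_nat * B_pr)

    # instantaneous maximum predation mortality on omnivores (at p = 0):
    # predator population per-capita capture rate per unit prey
    pr_spec = pr.prey[0]
    m_pred_inst = (
        pr_beh.f_feed * pr.f_veg * pr_spec.c * (1.0 - pr_beh.feeding_level) * B_pr
    )

    # --- external input / output -----------------------------------------
    fx.transfer(None, "nutrient", forcing.nutrient_load)
    if lw.flush > 0.0:
        fx.transfer("nutrient", None, lw.flush * P["nutrient"])
        fx.transfer("phytoplankton", None, lw.flush * P["phytoplankton"])

    # --- apply, scaling down overdrawn pools ------------------------------
    # Outflows computed from the current state may overdraw a small pool in
    # one Euler step; all outflows of such a pool are scaled by a common
    # factor, which preserves pairwise conservation exactly.
    new_pools = dict(P)
    for k in P:
        if P[k] + fx.delta[k] * dt < 0.0:
            _rescale_pool_outflows(fx, k, dt)
    clipped = 0.0
    for k in P:
        v = P[k] + fx.delta[k] * dt
        if v < POOL_FLOOR:
            # keep once-positive pools revivable; empty pools stay empty
            target = POOL_FLOOR if P[k] > 0.0 else 0.0
            if v != target:
                clipped += target - v
                v = target
        new_pools[k] = v

    m_pred_s = smooth_predation(state.m_pred_s, m_pred_inst)
    new_state = FoodWebState(pools=new_pools, m_pred_s=m_pred_s, time=state.time + dt)
    diag = {
        "omnivore": om_beh,
        "predator": pr_beh,
        "omnivore_diet": om_diet,
        "predator_diet": pr_diet,
        "m_pred_inst": m_pred_inst,
        "import_mass": fx.imports * dt,
        "export_mass": fx.export * dt,
        "clipped_mass": clipped,
    }
    if not all(math.isfinite(v) for v in new_pools.values()):
        raise FloatingPointError(f"non-finite state at t={new_state.time}: {new_pools}")
    return new_state, diag


def _rescale_pool_outflows(fx: _Fluxes, pool: str, dt: float) -> None:
    """Crude overdraw guard: shrink the net drain on ``pool`` to empty it.

    The deficit is charged against the pool's net loss; the matched gain is
    removed from the destination pools in proportion to their share of the
    step's positive deltas, keeping the step conservative.  This only
    engages for pools within one Euler step of zero, where the detailed
    routing of the last fraction of mass is immaterial.
    """
    net = fx.delta[pool]
    target_net = -fx.pools[pool] / dt
    excess = target_net - net  # > 0: mass that must not leave after all
    fx.delta[pool] = target_net
    gains = {k: d for k, d in fx.delta.items() if k != pool and d > 0.0}
    total_gain = sum(gains.values()) + max(fx.export, 0.0)
    if total_gain <= 0.0:
        # nothing received the mass (pathological); push it to sediment
        fx.delta["sediment_pom"] += excess
        return
    for k, d in gains.items():
        fx.delta[k] -= excess * (d / total_gain)
    fx.export -= excess * (max(fx.export, 0.0) / total_gain)


def run(
    cfg: LakeConfig,
    years: int = 100,
    dt: float = 1.0,
    seed: int | None = None,
    analysis_fraction: float = 0.5,
    initial: dict | None = None,
) -> ScenarioResult:
    """Simulate ``years`` of looped annual forcing and collect daily output.

    The forcing cycle is identical every year; the analysis window defaults
    to the last half of the run.  ``seed`` only enters the run metadata --
    the model is deterministic -- but is accepted so scripted protocols can
    thread one through uniformly.
    """
    if years < 2:
        raise ValueError("years must be >= 2")
    steps_per_year = int(round(DAYS_PER_YEAR / dt))
    table = annual_table(cfg.forcing, cfg.load_scale)
    forc = [
        ForcingSample(
            day_of_year=int(r.day_of_year),
            temperature=float(r.temperature),
            light_factor=float(r.light_factor),
            nutrient_load=float(r.nutrient_load),
        )
        for r in table.itertuples()
    ]

    pools = dict(DEFAULT_INITIAL)
    pools.update(cfg.initial)
    if initial:
        pools.update(initial)
    state = FoodWebState(pools=pools)

    n = years * steps_per_year
    cols = list(POOLS) + [
        "omnivore_p", "omnivore_f_feed", "omnivore_g", "predator_p",
        "predator_f_feed", "predator_g", "m_pred_s",
    ]
    data = np.empty((n, len(cols)))
    day_of_year = np.empty(n, dtype=int)
    year = np.empty(n, dtype=int)
    regime_counts = {r.value: 0 for r in Regime}
    cum_import = cum_export = cum_clip = 0.0

    i = 0
    for y in range(years):
        for d in range(steps_per_year):
            f = forc[int(d * dt) % DAYS_PER_YEAR]
            state, diag = step(state, f, cfg, dt)
            ob = diag["omnivore"]
            pb = diag["predator"]
            data[i, : len(POOLS)] = [state.pools[k] for k in POOLS]
            data[i, len(POOLS):] = [
                ob.p_star, ob.f_feed, ob.g, pb.p_star, pb.f_feed, pb.g,
                state.m_pred_s,
            ]
            day_of_year[i] = f.day_of_year
            year[i] = y
            regime_counts[ob.regime.value] += 1
            cum_import += diag["import_mass"]
            cum_export += diag["export_mass"]
            cum_clip += diag["clipped_mass"]
            i += 1

    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "time", np.arange(1, n + 1) * dt)
    df.insert(1, "year", year)
    df.insert(2, "day_of_year", day_of_year)
    meta = {
        "years": years,
        "dt": dt,
        "seed": seed,
        "load_scale": cfg.load_scale,
        "obm": {"omnivore": cfg.omnivore.obm, "predator": cfg.predator.obm},
        "regime_days": regime_counts,
        "import_mass": cum_import,
        "export_mass": cum_export,
        "clipped_mass": cum_clip,
        "final_total_mass": state.total_mass(),
    }
    return ScenarioResult(
        series=df,
        analysis_start_year=int(years * (1.0 - analysis_fraction)),
        meta=meta,
    )


def with_obm(cfg: LakeConfig, omnivore: bool, predator: bool | None = None) -> LakeConfig:
    """Copy of ``cfg`` with the behavioral model toggled per fish group."""
    if predator is None:
        predator = omnivore
    return replace(
        cfg,
        omnivore=replace(cfg.omnivore, obm=omnivore),
        predator=replace(cfg.predator, obm=predator),
    )
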