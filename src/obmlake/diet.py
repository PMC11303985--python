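"""Multi-prey feeding: diet breadth, feeding-mode allocation, and the
collapse of a mixed menu into the single-prey optimal-behavior problem.

Feeding decisions are made in two steps, in a fixed order.  First, with
feeding assumed maximized (no predation mitigation), the optimal diet is
chosen within each feeding mode and foraging time is allocated among modes
in proportion to the ingestion each mode would yield.  Second, the selected
menu is collapsed into aggregate encounter and quality terms and the
single-prey optimal-behavior model is solved on those aggregates.

Diet choice follows the classic prey-choice (zero-one) rule of the
contingency model for a gut-limited forager: prey are ranked by
profitability -- assimilated energy per unit gut occupation, ``a_i /
f_gut_i`` -- and added while total assimilation increases.  Because the
aggregate assimilation rate is a ratio of sums that is monotone in this
ranking, the greedy diet is the true subset optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .behavior import (
    BehaviorSolution,
    FeedingEnvironment,
    TradeoffParams,
    feeding_activity,
    feeding_level,
    fitness,
    ingestion,
    optimal_p,
    total_metabolism,
    total_mortality,
)

__all__ = [
    "PreyItem",
    "DietSolution",
    "aggregate_feeding_level",
    "optimal_diet",
    "allocate_modes",
    "diet_then_behavior",
]

MODES = ("pelagic", "benthic", "piscivorous")


@dataclass(frozen=True)
class PreyItem:
    """One food type as perceived by a fish group.

    ``f_gut`` is the gut-occupation factor: higher for prey of low
    digestibility or energy density.  Prey with ``f_gut = 0`` occupy no gut
    capacity and are always worth including.
    """

    id: str
    R: float
    c: float
    f_gut: float
    a: float
    mode: str = "pelagic"

    def __post_init__(self) -> None:
        for name in ("R", "c", "f_gut", "a"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.a > 1.0:
            raise ValueError(f"a must be <= 1, got {self.a}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass
class DietSolution:
    """Selected diet, mode allocation, and aggregate feeding terms."""

    included: dict[str, list[str]]
    mode_weights: dict[str, float]
    F_agg: float
    g_pot_agg: float
    per_prey_ingestion: dict[str, float] = field(default_factory=dict)
    per_prey_capture: dict[str, float] = field(default_factory=dict)


def aggregate_feeding_level(
    prey: list[PreyItem], i_max: float, f_feed: float = 1.0, f_veg: float = 1.0
) -> float:
    """Gut saturation for a mixed menu.

    ``F = L / (I_max + L)`` with gut load
    ``L = sum_i f_feed * f_veg * c_i * f_gut_i * R_i``.  Reduces to the
    single-prey feeding level for a one-item menu, and an empty menu gives 0.
    """
    load = sum(f_feed * f_veg * p.c * p.f_gut * p.R for p in prey)
    if load == 0.0:
        return 0.0
    if i_max == 0.0:
        raise ValueError("i_max = 0 with positive encountered gut load")
    return load / (i_max + load)


def _diet_assimilation(prey: list[PreyItem], i_max: float, f_veg: float) -> float:
    """Total assimilation rate of a menu at maximized feeding (f_feed = 1)."""
    if not prey:
        return 0.0
    F = aggregate_feeding_level(prey, i_max, 1.0, f_veg)
    return sum(p.a * p.c * f_veg * p.R * (1.0 - F) for p in prey)


def optimal_diet(
    prey_in_mode: list[PreyItem], i_max: float, f_veg: float = 1.0
) -> list[PreyItem]:
    """Subset of one mode's prey maximizing total assimilated energy.

    Feeding is assumed maximized (``f_feed = 1``); the mitigation decision
    comes afterwards.  Prey are ranked by profitability ``a_i / f_gut_i``
    (ties broken by larger encounter ``c_i * R_i``) and appended while the
    menu's total assimilation increases; zero-gut-cost prey always enter.
    The result is the exhaustive-search optimum.
    """
    free = [p for p in prey_in_mode if p.f_gut == 0.0]
    costly = [p for p in prey_in_mode if p.f_gut > 0.0]
    costly.sort(key=lambda p: (p.a / p.f_gut, p.c * p.R), reverse=True)
    chosen = list(free)
    best = _diet_assimilation(chosen, i_max, f_veg)
    for p in costly:
        trial = _diet_assimilation(chosen + [p], i_max, f_veg)
        if trial > best:
            chosen.append(p)
            best = trial
        else:
            break  # profitability ranking: later prey cannot help either
    return chosen


def allocate_modes(mode_ingestion: dict[str, float]) -> dict[str, float]:
    """Foraging-time weights: a weighted average of relative ingestion rates.

    ``w_m = g_m / sum(g)``; if every mode yields zero, time is split
    uniformly over the available modes.
    """
    if not mode_ingestion:
        return {}
    if any(g < 0.0 for g in mode_ingestion.values()):
        raise ValueError("mode ingestion rates must be >= 0")
    total = sum(mode_ingestion.values())
    if total == 0.0:
        w = 1.0 / len(mode_ingestion)
        return {m: w for m in mode_ingestion}
    return {m: g / total for m, g in mode_ingestion.items()}


def diet_then_behavior(
    prey: list[PreyItem],
    *,
    i_max: float,
    u: float,
    m_nat: float,
    m_pred_s: float,
    tp: TradeoffParams,
    f_veg: float = 1.0,
    p_fixed: float | None = None,
) -> tuple[DietSolution, BehaviorSolution]:
    """Two-step decision: diet and mode allocation first, then behavior.

    Step 1 selects the optimal diet within each feeding mode and allocates
    foraging time among modes by their relative ingestion, all at maximized
    feeding.  Step 2 collapses the selected, time-weighted menu into
    aggregate encounter (``sum w_m c_i f_gut_i R_i``) and encounter-weighted
    mean assimilation and gut-quality terms, and solves the single-prey
    optimal-behavior model on these aggregates.  Because the multi-prey
    ingestion shares one feeding level, the collapse is exact for the fixed
    diet: realized ingestion distributes over prey in proportion to their
    contribution to assimilated encounter.

    With ``p_fixed`` given, step 2 evaluates the behavior at that mitigation
    level instead of optimizing -- ``p_fixed = 0`` is the classical control
    model that always feeds maximally.
    """
    by_mode: dict[str, list[PreyItem]] = {}
    for p in prey:
        by_mode.setdefault(p.mode, []).append(p)

    included: dict[str, list[str]] = {}
    diets: dict[str, list[PreyItem]] = {}
    mode_g: dict[str, float] = {}
    for mode, items in by_mode.items():
        chosen = optimal_diet(items, i_max, f_veg)
        diets[mode] = chosen
        included[mode] = [p.id for p in chosen]
        mode_g[mode] = _diet_assimilation(chosen, i_max, f_veg)
    weights = allocate_modes(mode_g)

    # time-weighted effective menu: prey i in mode m contributes w_m * c_i
    cr = 0.0   # encounter sum_m w_m c_i R_i
    gut = 0.0  # gut-weighted encounter
    ae = 0.0   # assimilation-weighted encounter
    for mode, chosen in diets.items():
        w = weights[mode]
        for p in chosen:
            cr += w * p.c * p.R
            gut += w * p.c * p.f_gut * p.R
            ae += w * p.a * p.c * p.R

    if cr > 0.0:
        env = FeedingEnvironment(
            R=1.0, c=cr, f_gut=gut / cr, f_veg=f_veg, i_max=i_max,
            a=ae / cr, u=u, m_nat=m_nat, m_pred_s=m_pred_s,
        )
    else:
        env = FeedingEnvironment(
            R=0.0, c=0.0, f_gut=0.0, f_veg=f_veg, i_max=i_max,
            a=0.0, u=u, m_nat=m_nat, m_pred_s=m_pred_s,
        )
    if p_fixed is None:
        behavior = optimal_p(env, tp)
    else:
        f_feed = feeding_activity(p_fixed, tp.f_fc)
        W, regime = fitness(p_fixed, env, tp)
        behavior = BehaviorSolution(
            p_star=p_fixed,
            f_feed=f_feed,
            feeding_level=feeding_level(env, f_feed),
            g=ingestion(env, f_feed),
            u_tot=total_metabolism(env.u, tp.f_rf, f_feed),
            m_tot=total_mortality(p_fixed, tp.f_pm, env.m_nat, env.m_pred_s),
            regime=regime,
            fitness=W,
        )

    # distribute realized ingestion over prey by assimilated-encounter share
    per_assim: dict[str, float] = {}
    per_capture: dict[str, float] = {}
    load = behavior.f_feed * f_veg * gut
    hunger = i_max / (i_max + load) if load > 0.0 else 1.0
    for mode, chosen in diets.items():
        w = weights[mode]
        for p in chosen:
            per_capture[p.id] = behavior.f_feed * f_veg * w * p.c * p.R * hunger
            per_assim[p.id] = p.a * per_capture[p.id]

    diet = DietSolution(
        included=included,
        mode_weights=weights,
        F_agg=feeding_level(env, 1.0),
        g_pot_agg=ingestion(env, 1.0),
        per_prey_ingestion=per_assim,
        per_prey_capture=per_capture,
    )
    return diet, behavior
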