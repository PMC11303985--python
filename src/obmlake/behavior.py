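"""Optimal fish-behavior model: the feeding vs. predation-mitigation trade-off.

A fish population chooses a position ``p`` on a behavioral gradient between
maximal feeding (``p = 0``) and maximal predation mitigation (``p = 1``).
Mitigation reduces feeding activity (by a factor ``f_FC``), predation
mortality (by ``f_PM``) and, indirectly, the metabolic cost of foraging
(``f_RF`` times the basal rate per unit of feeding activity).

Fitness follows Gilliam's rule -- net specific energy gain divided by total
mortality -- whenever feeding at full effort would yield a non-negative net
gain; under starvation conditions the proxy degrades to the net gain itself.
The optimum ``p*`` is found exactly: the stationarity condition of the
fitness ratio is a cubic polynomial in ``p``, and the solver compares the
fitness at its real roots inside [0, 1] with the interval endpoints.

All rates are biomass-specific (d^-1); concentrations are g m^-3.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TradeoffParams",
    "FeedingEnvironment",
    "BehaviorSolution",
    "Regime",
    "feeding_activity",
    "feeding_level",
    "ingestion",
    "total_mortality",
    "smooth_predation",
    "total_metabolism",
    "fitness",
    "optimal_p",
    "emergent_functional_response",
]

#: absolute tolerance for regime-threshold comparisons on specific rates (d^-1)
RATE_ATOL = 1e-12

#: fitness plateaus flatter than this are broken toward the largest (safest) p
TIE_TOL = 1e-12


class Regime(enum.Enum):
    """Which branch of the fitness criterion applies."""

    NORMAL = "normal"
    STARVATION_FEED = "starvation_feed"
    STARVATION_STOP = "starvation_stop"


@dataclass(frozen=True)
class TradeoffParams:
    """Strength of the behavioral trade-off for one fish group.

    Parameters
    ----------
    f_pm : float
        Predation-mitigation efficiency in [0, 1]; at ``p = 1`` predation
        mortality is reduced by this fraction.
    f_fc : float
        Feeding cost of mitigation in [0, 1]; at ``p = 1`` feeding activity
        drops to ``1 - f_fc``.
    f_rf : float
        Extra metabolic cost of active feeding, relative to the basal
        metabolic rate (>= 0).
    """

    f_pm: float
    f_fc: float
    f_rf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_pm <= 1.0:
            raise ValueError(f"f_pm must be in [0, 1], got {self.f_pm}")
        if not 0.0 <= self.f_fc <= 1.0:
            raise ValueError(f"f_fc must be in [0, 1], got {self.f_fc}")
        if self.f_rf < 0.0:
            raise ValueError(f"f_rf must be >= 0, got {self.f_rf}")


@dataclass(frozen=True)
class FeedingEnvironment:
    """Ambient state perceived by one fish group in one time step.

    Attributes
    ----------
    R : float
        Prey availability (g m^-3).
    c : float
        Maximum clearance rate (m^3 g^-1 d^-1 per unit predator biomass).
    f_gut : float
        Gut-occupation factor (dimensionless, >= 0); higher for prey of low
        digestibility or energy density.
    f_veg : float
        Vegetation catchability factor in [0, 1] (1 = open water).
    i_max : float
        Temperature-scaled maximum (gut-limited) consumption (d^-1).
    a : float
        Assimilation efficiency in [0, 1].
    u : float
        Basal temperature-scaled metabolic rate (d^-1).
    m_nat : float
        Background natural mortality (d^-1); must be > 0 wherever the
        Gilliam ratio is evaluated.
    m_pred_s : float
        Smoothed maximum predation mortality (d^-1), i.e. the mortality the
        group would suffer at ``p = 0``.
    """

    R: float
    c: float
    f_gut: float
    f_veg: float = 1.0
    i_max: float = 1.0
    a: float = 1.0
    u: float = 0.0
    m_nat: float = 1e-3
    m_pred_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("R", "c", "f_gut", "f_veg", "i_max", "a", "u", "m_nat", "m_pred_s"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.f_veg > 1.0:
            raise ValueError(f"f_veg must be <= 1, got {self.f_veg}")
        if self.a > 1.0:
            raise ValueError(f"a must be <= 1, got {self.a}")

    @property
    def encounter(self) -> float:
        """Encountered prey R_e = R * c * f_veg (d^-1 before gut weighting)."""
        return self.R * self.c * self.f_veg


@dataclass(frozen=True)
class BehaviorSolution:
    """The optimal behavior and the rates realized at it."""

    p_star: float
    f_feed: float
    feeding_level: float
    g: float
    u_tot: float
    m_tot: float
    regime: Regime
    fitness: float


def feeding_activity(p: float, f_fc: float) -> float:
    """Feeding activity ``f_feed = 1 - p * f_FC`` at mitigation level ``p``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0.0 <= f_fc <= 1.0:
        raise ValueError(f"f_fc must be in [0, 1], got {f_fc}")
    return 1.0 - p * f_fc


def feeding_level(env: FeedingEnvironment, f_feed: float) -> float:
    """Gut saturation F in [0, 1): encountered gut load over capacity.

    ``F = f_feed*f_veg*c*f_gut*R / (I_max + f_feed*f_veg*c*f_gut*R)``.
    """
    if not 0.0 <= f_feed <= 1.0:
        raise ValueError(f"f_feed must be in [0, 1], got {f_feed}")
    load = f_feed * env.f_veg * env.c * env.f_gut * env.R
    if load == 0.0:
        return 0.0
    if env.i_max == 0.0:
        raise ValueError("i_max = 0 with positive encountered gut load")
    return load / (env.i_max + load)


def ingestion(env: FeedingEnvironment, f_feed: float) -> float:
    """Specific assimilation rate g (d^-1) at feeding activity ``f_feed``.

    Encountered-and-caught prey, times the hunger level (1 - F), times the
    assimilation efficiency.  With ``f_feed = 1`` this is algebraically a
    Holling type II response with handling time ``f_gut / I_max`` and attack
    rate ``f_veg * c``.
    """
    if not 0.0 <= f_feed <= 1.0:
        raise ValueError(f"f_feed must be in [0, 1], got {f_feed}")
    load = f_feed * env.f_veg * env.c * env.f_gut * env.R
    if load > 0.0 and env.i_max == 0.0:
        raise ValueError("i_max = 0 with positive encountered gut load")
    # hunger level 1 - F, formed directly to avoid cancellation near satiation
    hunger = env.i_max / (env.i_max + load) if load > 0.0 else 1.0
    return env.a * f_feed * env.f_veg * env.c * env.R * hunger


def total_mortality(p: float, f_pm: float, m_nat: float, m_pred_s: float) -> float:
    """Total mortality ``m_nat + (1 - p*f_PM) * m_pred_s`` (d^-1)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0.0 <= f_pm <= 1.0:
        raise ValueError(f"f_pm must be in [0, 1], got {f_pm}")
    if m_nat < 0.0 or m_pred_s < 0.0:
        raise ValueError("mortality rates must be >= 0")
    return m_nat + (1.0 - p * f_pm) * m_pred_s


def smooth_predation(m_pred_s_prev: float, m_pred: float) -> float:
    """One step of the predation-mortality smoother.

    ``m_s <- (m_s_prev + 0.25 * m_pred) / 1.25`` -- an exponential relaxation
    toward the instantaneous rate with per-step factor 0.8, damping erratic
    switching of prey and predator feeding efforts between time steps.
    """
    if m_pred_s_prev < 0.0 or m_pred < 0.0:
        raise ValueError("predation rates must be >= 0")
    return (m_pred_s_prev + 0.25 * m_pred) / 1.25


def total_metabolism(u: float, f_rf: float, f_feed: float) -> float:
    """Total metabolic rate ``(1 + f_RF * f_feed) * u`` (d^-1)."""
    if u < 0.0 or f_rf < 0.0:
        raise ValueError("u and f_rf must be >= 0")
    return (1.0 + f_rf * f_feed) * u


def _net_gain(p: float, env: FeedingEnvironment, tp: TradeoffParams) -> float:
    f_feed = feeding_activity(p, tp.f_fc)
    return ingestion(env, f_feed) - total_metabolism(env.u, tp.f_rf, f_feed)


def fitness(p: float, env: FeedingEnvironment, tp: TradeoffParams) -> tuple[float, Regime]:
    """Fitness W of mitigation level ``p`` and the regime that applies.

    When the potential net gain at full feeding (``p = 0``) is non-negative,
    W is Gilliam's rule, net gain over total mortality.  When it is negative
    the immediate concern is starvation, predation is disregarded, and W is
    the net gain itself; the regime distinguishes whether feeding still pays
    its own marginal cost (``starvation_feed``) or not (``starvation_stop``).
    """
    g_pot = ingestion(env, 1.0)
    u_pot = total_metabolism(env.u, tp.f_rf, 1.0)
    net_pot = g_pot - u_pot
    if net_pot >= -RATE_ATOL:
        m_tot = total_mortality(p, tp.f_pm, env.m_nat, env.m_pred_s)
        if m_tot <= 0.0:
            raise ValueError("total mortality is 0; Gilliam ratio undefined (need m_nat > 0)")
        return _net_gain(p, env, tp) / m_tot, Regime.NORMAL
    if net_pot > -env.u + RATE_ATOL:
        return _net_gain(p, env, tp), Regime.STARVATION_FEED
    return -env.u, Regime.STARVATION_STOP


def _stationary_points(env: FeedingEnvironment, tp: TradeoffParams) -> np.ndarray:
    """Real roots in (0, 1) of d/dp of the Gilliam ratio.

    With f_feed = 1 - q*p (q = f_FC), E = c*f_gut*f_veg*R, A = a*c*f_veg*R*I_max,
    D(p) = I_max + E*f_feed and m(p) = m_nat + (1 - p*f_PM)*m_pred_s, the
    numerator of W'(p) times D(p)^2 is the cubic

        C(p) = -q * (A*I_max - f_RF*u*D^2) * m  +  f_PM*m_pred_s * (A*f_feed*D - (1 + f_RF*f_feed)*u*D^2)
    """
    q = tp.f_fc
    E = env.c * env.f_gut * env.f_veg * env.R
    A = env.a * env.c * env.f_veg * env.R * env.i_max
    I = env.i_max
    u = env.u
    s = env.m_pred_s

    # polynomials in p, ascending coefficients
    D = np.array([I + E, -E * q])                      # I + E*(1 - q p)
    f = np.array([1.0, -q])
    m = np.array([env.m_nat + s, -tp.f_pm * s])
    D2 = np.polynomial.polynomial.polymul(D, D)
    term1 = np.polynomial.polynomial.polymul(
        np.polynomial.polynomial.polysub(np.array([A * I]), tp.f_rf * u * D2), m
    ) * (-q)
    fD = np.polynomial.polynomial.polymul(f, D)
    one_rf = np.polynomial.polynomial.polyadd(np.array([1.0]), tp.f_rf * f)
    term2 = (tp.f_pm * s) * np.polynomial.polynomial.polysub(
        A * fD, u * np.polynomial.polynomial.polymul(one_rf, D2)
    )
    coeffs = np.polynomial.polynomial.polyadd(term1, term2)
    top = np.max(np.abs(coeffs))
    if top == 0.0 or not np.isfinite(top):
        return np.empty(0)
    coeffs = coeffs / top
    # drop relatively negligible leading-order terms; they only destabilize
    # the companion-matrix eigenproblem without moving roots inside [0, 1]
    while coeffs.size > 1 and abs(coeffs[-1]) < 1e-14:
        coeffs = coeffs[:-1]
    if coeffs.size <= 1:
        return np.empty(0)
    try:
        roots = np.polynomial.polynomial.polyroots(coeffs)
    except np.linalg.LinAlgError:
        # pathologically scaled input: fall back to a dense candidate set,
        # which the caller's argmax-over-candidates handles exactly enough
        return np.linspace(0.0, 1.0, 513)[1:-1]
    real = roots[np.abs(roots.imag) < 1e-9].real
    return real[(real > 0.0) & (real < 1.0)]


def optimal_p(env: FeedingEnvironment, tp: TradeoffParams) -> BehaviorSolution:
    """Solve for the fitness-maximizing mitigation level ``p*``.

    Regime logic:

    * ``starvation_stop`` -- feeding cannot pay its own marginal cost
      (``g_pot <= f_RF * u``): the fish stops feeding (``f_feed = 0``) and is
      free to mitigate fully (``p* = 1``).
    * ``starvation_feed`` -- net gain at full feeding is negative but feeding
      still beats fasting: the fish maximizes time to starvation by feeding
      maximally (``p* = 0``).
    * ``normal`` -- the Gilliam ratio is maximized exactly over [0, 1] by
      comparing its value at the cubic stationary points and the endpoints.

    Plateaus flat to within ``TIE_TOL`` resolve to the largest ``p``
    (mortality weakly decreases in ``p``).
    """
    if env.m_nat <= 0.0:
        raise ValueError("m_nat must be > 0 for the optimal-behavior solution")
    g_pot = ingestion(env, 1.0)
    u_pot = total_metabolism(env.u, tp.f_rf, 1.0)
    net_pot = g_pot - u_pot

    if net_pot <= -env.u + RATE_ATOL:
        # Eq.-(8)-type branch: stop feeding, mitigate fully.
        m_tot = total_mortality(1.0, tp.f_pm, env.m_nat, env.m_pred_s)
        return BehaviorSolution(
            p_star=1.0, f_feed=0.0, feeding_level=0.0, g=0.0, u_tot=env.u,
            m_tot=m_tot, regime=Regime.STARVATION_STOP, fitness=-env.u,
        )
    if net_pot < -RATE_ATOL:
        # Negative net gain but feeding still pays: maximize feeding.
        m_tot = total_mortality(0.0, tp.f_pm, env.m_nat, env.m_pred_s)
        return BehaviorSolution(
            p_star=0.0, f_feed=1.0, feeding_level=feeding_level(env, 1.0),
            g=g_pot, u_tot=u_pot, m_tot=m_tot,
            regime=Regime.STARVATION_FEED, fitness=net_pot,
        )

    candidates = np.concatenate([[0.0, 1.0], _stationary_points(env, tp)])

    def ratio(p: float) -> float:
        return _net_gain(p, env, tp) / total_mortality(p, tp.f_pm, env.m_nat, env.m_pred_s)

    values = np.array([ratio(p) for p in candidates])
    best = values.max()
    # among near-ties prefer the largest p (safest behavior)
    p_star = float(candidates[values >= best - TIE_TOL].max())
    f_feed = feeding_activity(p_star, tp.f_fc)
    return BehaviorSolution(
        p_star=p_star,
        f_feed=f_feed,
        feeding_level=feeding_level(env, f_feed),
        g=ingestion(env, f_feed),
        u_tot=total_metabolism(env.u, tp.f_rf, f_feed),
        m_tot=total_mortality(p_star, tp.f_pm, env.m_nat, env.m_pred_s),
        regime=Regime.NORMAL,
        fitness=best,
    )


def emergent_functional_response(
    env_template: FeedingEnvironment,
    tp: TradeoffParams,
    R_grid,
):
    """Consumption-vs-availability curve after behavioral optimization.

    For each availability in ``R_grid`` (ascending) the optimal behavior is
    solved and the realized consumption (caught prey before assimilation,
    ``f_feed*f_veg*c*R*(1-F)``) is reported scaled by the maximum consumption
    ``I_max``; availability is reported scaled as encountered prey over
    ``I_max``.  Below the starvation threshold consumption is zero.

    Returns a :class:`pandas.DataFrame` with columns ``R``,
    ``scaled_availability``, ``p_star``, ``f_feed``, ``scaled_consumption``
    and ``regime``.
    """
    import pandas as pd

    R_grid = np.asarray(R_grid, dtype=float)
    if R_grid.ndim != 1 or np.any(np.diff(R_grid) < 0):
        raise ValueError("R_grid must be a 1-D ascending array")
    rows = []
    for R in R_grid:
        env = FeedingEnvironment(
            R=float(R), c=env_template.c, f_gut=env_template.f_gut,
            f_veg=env_template.f_veg, i_max=env_template.i_max,
            a=env_template.a, u=env_template.u, m_nat=env_template.m_nat,
            m_pred_s=env_template.m_pred_s,
        )
        sol = optimal_p(env, tp)
        consumption = sol.g / env.a if env.a > 0 else 0.0
        rows.append(
            {
                "R": float(R),
                "scaled_availability": env.encounter / env.i_max,
                "p_star": sol.p_star,
                "f_feed": sol.f_feed,
                "scaled_consumption": consumption / env.i_max,
                "regime": sol.regime.value,
            }
        )
    return pd.DataFrame(rows)
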