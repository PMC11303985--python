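"""Scenario protocols: trade-off sweeps, nutrient-loading ladders, and
emergent functional-response curves.

Every protocol runs each scenario cell independently with the shared
spin-up convention (run ``years`` of looped forcing, analyze the last
``analysis_fraction``), so results do not depend on cell execution order.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .behavior import FeedingEnvironment, TradeoffParams, emergent_functional_response
from .foodweb import LakeConfig, run, with_obm
from .stats import between_year_cv, scenario_metrics, within_year_cv

__all__ = ["sweep", "loading_ladder", "response_curves", "LOAD_SCALES"]

#: the standard nutrient-load ladder (fractions of the baseline load)
LOAD_SCALES = (0.25, 0.5, 1.0, 2.0, 4.0)

_SWEEP_VARS = ("phytoplankton", "zooplankton", "zoobenthos", "omnivore", "predator")


def _cell_summary(result) -> dict:
    an = result.analysis
    out = {}
    for v in _SWEEP_VARS:
        vals = an[v].values
        out[f"{v}_mean"] = float(an[v].mean())
        try:
            out[f"{v}_cv_within"] = within_year_cv(vals)
            out[f"{v}_cv_between"] = between_year_cv(vals)
        except ValueError:
            out[f"{v}_cv_within"] = np.nan
            out[f"{v}_cv_between"] = np.nan
    return out


def sweep(
    cfg: LakeConfig,
    f_pm_values,
    f_fc_values,
    years: int = 100,
    seed: int = 0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Mean-biomass and CV surfaces over an omnivore f_PM x f_FC grid.

    Each grid cell reruns the scenario with the omnivore trade-off replaced
    (the predator's trade-off is left alone: as top predator its behavior
    is pure energetics).  When ``include_control`` is set, one extra row
    with ``control = True`` holds the no-behavior solution for isoline-style
    comparison.  Cells that fail numerically are recorded with ``error`` set
    and the sweep continues.
    """
    rows = []
    for f_pm in f_pm_values:
        for f_fc in f_fc_values:
            tp = replace(cfg.omnivore.tradeoff, f_pm=float(f_pm), f_fc=float(f_fc))
            cell_cfg = replace(cfg, omnivore=replace(cfg.omnivore, tradeoff=tp, obm=True),
                               predator=replace(cfg.predator, obm=True))
            row = {"f_pm": float(f_pm), "f_fc": float(f_fc), "control": False, "error": ""}
            try:
                res = run(cell_cfg, years=years, seed=seed)
                row.update(_cell_summary(res))
            except Exception as exc:  # per-cell failure must not kill the sweep
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    if include_control:
        row = {"f_pm": np.nan, "f_fc": np.nan, "control": True, "error": ""}
        res = run(with_obm(cfg, False), years=years, seed=seed)
        row.update(_cell_summary(res))
        rows.append(row)
    return pd.DataFrame(rows)


def loading_ladder(
    cfg: LakeConfig,
    scales=LOAD_SCALES,
    years: int = 60,
    seed: int = 0,
    configurations: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Seasonal food-web metrics along the nutrient-loading ladder.

    Runs every load scale for each named configuration (by default
    ``optimal_behavior`` and ``no_behavior``) and returns a tidy table of
    :func:`~obmlake.stats.scenario_metrics` rows, plus the omnivore-biomass
    index normalized to the maximum across configurations.
    """
    configurations = configurations or {"optimal_behavior": True, "no_behavior": False}
    rows = []
    for name, obm in configurations.items():
        for s in scales:
            res = run(replace(with_obm(cfg, obm), load_scale=float(s)), years=years, seed=seed)
            m = scenario_metrics(res, cfg.chlorophyll_per_biomass)
            for _, r in m.iterrows():
                rows.append({"configuration": name, "load_scale": float(s),
                             "metric": r["metric"], "value": r["value"]})
    df = pd.DataFrame(rows)
    omni = df[df["metric"] == "august_omnivore_biomass"]
    peak = omni["value"].max()
    if peak > 0:
        idx = omni.assign(metric="omnivore_biomass_index", value=omni["value"] / peak)
        df = pd.concat([df, idx], ignore_index=True)
    return df


def response_curves(
    tp: TradeoffParams,
    m_pred_levels=(0.001, 0.01),
    R_max_factor: float = 3.0,
    n_points: int = 200,
    env_template: FeedingEnvironment | None = None,
) -> pd.DataFrame:
    """Emergent functional-response curves at several ambient risk levels.

    Availability runs from near zero to ``R_max_factor`` times the
    half-saturation availability; one block of rows per ``m_pred_s`` level.
    """
    base = env_template or FeedingEnvironment(
        R=1.0, c=1.0, f_gut=1.0, f_veg=1.0, i_max=1.0, a=0.7, u=0.01, m_nat=0.001
    )
    R_half = base.i_max / (base.c * base.f_gut * base.f_veg)
    R_grid = np.linspace(1e-3, R_max_factor * R_half, n_points)
    out = []
    for m in m_pred_levels:
        env = replace(base, m_pred_s=float(m))
        df = emergent_functional_response(env, tp, R_grid)
        df.insert(0, "m_pred_s", float(m))
        out.append(df)
    return pd.concat(out, ignore_index=True)
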