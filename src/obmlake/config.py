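"""Declarative scenario configuration: YAML schema, validation, manifests.

A scenario file is a nested mapping with sections ``lower`` (plankton /
benthos closure rates), ``omnivore`` and ``predator`` (fish groups, each
with a ``tradeoff`` block and a ``prey`` menu), ``forcing`` (three
sinusoidal channels), and ``run`` (years, time step, analysis fraction,
seed, nutrient ``load_scale``).  Any omitted key falls back to the package
default, so a file only needs to state what it changes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .behavior import TradeoffParams
from .foodweb import GroupConfig, LakeConfig, LowerWebConfig, PreySpec
from .forcing import ChannelParams, ForcingParams

__all__ = [
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
    "RunManifest",
    "DEFAULT_RUN",
]

DEFAULT_RUN = {
    "years": 100,
    "dt": 1.0,
    "analysis_fraction": 0.5,
    "seed": 0,
}


def _channel(d: dict) -> ChannelParams:
    return ChannelParams(
        mean=float(d["mean"]),
        amplitude=float(d.get("amplitude", 0.0)),
        phase=float(d.get("phase", 0.0)),
        floor=None if d.get("floor") is None else float(d["floor"]),
    )


def _forcing(d: dict) -> ForcingParams:
    base = ForcingParams()
    return ForcingParams(
        temperature=_channel(d["temperature"]) if "temperature" in d else base.temperature,
        light=_channel(d["light"]) if "light" in d else base.light,
        load=_channel(d["load"]) if "load" in d else base.load,
    )


def _group(name: str, d: dict) -> GroupConfig:
    tp = d.get("tradeoff", {})
    prey = tuple(
        PreySpec(
            pool=str(p["pool"]),
            mode=str(p["mode"]),
            c=float(p["c"]),
            f_gut=float(p["f_gut"]),
            a=float(p["a"]),
        )
        for p in d["prey"]
    )
    return GroupConfig(
        name=name,
        i_max_ref=float(d["i_max_ref"]),
        u_ref=float(d["u_ref"]),
        m_nat=float(d["m_nat"]),
        q10=float(d.get("q10", 2.0)),
        tradeoff=TradeoffParams(
            f_pm=float(tp.get("f_pm", 1.0)),
            f_fc=float(tp.get("f_fc", 1.0)),
            f_rf=float(tp.get("f_rf", 0.0)),
        ),
        obm=bool(d.get("obm", True)),
        prey=prey,
        f_veg=float(d.get("f_veg", 1.0)),
    )


def config_from_dict(d: dict) -> tuple[LakeConfig, dict]:
    """Build a (LakeConfig, run-options) pair from a nested mapping."""
    if "omnivore" not in d or "predator" not in d:
        raise ValueError("config must define 'omnivore' and 'predator' groups")
    lower_kwargs = d.get("lower", {})
    unknown = set(lower_kwargs) - {f.name for f in dataclasses.fields(LowerWebConfig)}
    if unknown:
        raise ValueError(f"unknown keys in 'lower': {sorted(unknown)}")
    lake = LakeConfig(
        lower=LowerWebConfig(**{k: float(v) for k, v in lower_kwargs.items()}),
        omnivore=_group("omnivore", d["omnivore"]),
        predator=_group("predator", d["predator"]),
        forcing=_forcing(d.get("forcing", {})),
        load_scale=float(d.get("run", {}).get("load_scale", 1.0)),
        chlorophyll_per_biomass=float(d.get("chlorophyll_per_biomass", 10.0)),
        initial={k: float(v) for k, v in d.get("initial", {}).items()},
    )
    run_opts = dict(DEFAULT_RUN)
    for k in ("years", "dt", "analysis_fraction", "seed"):
        if k in d.get("run", {}):
            run_opts[k] = d["run"][k]
    run_opts["years"] = int(run_opts["years"])
    run_opts["seed"] = int(run_opts["seed"])
    return lake, run_opts


def config_to_dict(cfg: LakeConfig, run_opts: dict | None = None) -> dict:
    """Round-trippable plain-dict form of a configuration."""
    d = {
        "lower": asdict(cfg.lower),
        "omnivore": _group_dict(cfg.omnivore),
        "predator": _group_dict(cfg.predator),
        "forcing": {
            ch: asdict(getattr(cfg.forcing, ch)) for ch in ("temperature", "light", "load")
        },
        "chlorophyll_per_biomass": cfg.chlorophyll_per_biomass,
        "initial": dict(cfg.initial),
        "run": dict(run_opts or DEFAULT_RUN) | {"load_scale": cfg.load_scale},
    }
    return d


def _group_dict(g: GroupConfig) -> dict:
    return {
        "i_max_ref": g.i_max_ref,
        "u_ref": g.u_ref,
        "m_nat": g.m_nat,
        "q10": g.q10,
        "tradeoff": asdict(g.tradeoff),
        "obm": g.obm,
        "f_veg": g.f_veg,
        "prey": [asdict(p) for p in g.prey],
    }


def load_config(path: str | Path) -> tuple[LakeConfig, dict]:
    """Load and validate a YAML scenario file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)


def save_config(cfg: LakeConfig, run_opts: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg, run_opts), fh, sort_keys=True)


def config_hash(d: dict) -> str:
    """Short stable digest of a config mapping (key order irrelevant)."""
    canon = json.dumps(d, sort_keys=True, separators=(",", ":"), default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Sidecar metadata identifying one run's provenance."""

    config_hash: str
    seed: int
    version: str
    outputs: list[str]
    extra: dict = dataclasses.field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
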