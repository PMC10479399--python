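"""Run configuration: YAML/JSON files with validated, defaulted sections.

An empty file (or missing section) yields the published default
parameters throughout; unknown keys are rejected with the path to the
offending key so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .kinetics import (
    BellParams,
    CatchSlipParams,
    SubdomainSpec,
    DEFAULT_DX_UNFOLD,
    DEFAULT_K_UNFOLD0,
    DEFAULT_UNBIND,
)
from .mechanics import ChainConfig, MechanicalParams
from .pulling import SimParams

__all__ = ["RunConfig", "ConfigError", "parse_config"]


class ConfigError(ValueError):
    """A config file violates the schema; message names the key path."""


@dataclasses.dataclass
class AnalysisConfig:
    """SiMS analysis settings (mode, thresholds, flow geometry)."""

    mode: str = "coarse_2s"
    motion_threshold: float | None = None
    flow_axis: tuple = (1.0, 0.0)
    localization_sd: float = 18.6
    bleach_per_frame: float | None = 0.0071
    stationary_window: int = 8
    onset_threshold_factor: float = 2.0


@dataclasses.dataclass
class RunConfig:
    """Fully resolved configuration of one run."""

    mechanics: MechanicalParams
    chain: ChainConfig
    unfold: object               # BellParams | SubdomainSpec
    unbind: object               # BellParams | CatchSlipParams
    simulation: SimParams
    analysis: AnalysisConfig
    dt_master: float = 1e-3
    t_max: float = 600.0
    p_terminate: float = 0.999
    seed: int = 0

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {
            "mechanics": enc(self.mechanics),
            "chain": enc(self.chain),
            "unfold": enc(self.unfold),
            "unbind": enc(self.unbind),
            "simulation": enc(self.simulation),
            "analysis": enc(self.analysis),
            "master_equation": {
                "dt": self.dt_master,
                "t_max": self.t_max,
                "p_terminate": self.p_terminate,
            },
            "seed": self.seed,
        }
        d["unbind"]["model"] = (
            "catch_slip" if isinstance(self.unbind, CatchSlipParams) else "slip"
        )
        return d


def _build(cls, data: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def _parse_unbind(data: dict):
    data = dict(data)
    model = data.pop("model", "slip")
    if model == "slip":
        data.setdefault("k0", DEFAULT_UNBIND.k0)
        data.setdefault("dx", DEFAULT_UNBIND.dx)
        return _build(BellParams, data, "unbinding")
    if model == "catch_slip":
        return _build(CatchSlipParams, data, "unbinding")
    raise ConfigError(f"unbinding.model: must be 'slip' or 'catch_slip', got {model!r}")


def _parse_unfold(data, chain: ChainConfig):
    if isinstance(data, list):
        if len(data) != chain.n_total:
            raise ConfigError(
                f"subdomains: per-subdomain list has {len(data)} entries, "
                f"chain has {chain.n_total}"
            )
        params, unfoldable = [], []
        for i, entry in enumerate(data):
            entry = dict(entry)
            unfoldable.append(bool(entry.pop("unfoldable", True)))
            entry.setdefault("k0", DEFAULT_K_UNFOLD0)
            entry.setdefault("dx", DEFAULT_DX_UNFOLD)
            params.append(_build(BellParams, entry, f"subdomains[{i}]"))
        spec = SubdomainSpec(params=tuple(params), unfoldable=tuple(unfoldable))
        if spec.n_unfoldable != chain.n_unfoldable:
            raise ConfigError(
                f"subdomains: {spec.n_unfoldable} unfoldable entries but "
                f"chain.n_unfoldable = {chain.n_unfoldable}"
            )
        return spec
    data = dict(data or {})
    data.setdefault("k0", DEFAULT_K_UNFOLD0)
    data.setdefault("dx", DEFAULT_DX_UNFOLD)
    return _build(BellParams, data, "subdomains")


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML/JSON config file into a validated :class:`RunConfig`.

    Missing sections/keys take the published default values.  ``path``
    may be None (all defaults).  ``overrides`` is a nested dict merged
    on top of the file (CLI options use this).
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if text.strip() else None
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded
    for k, v in (overrides or {}).items():
        if isinstance(v, dict):
            raw.setdefault(k, {})
            raw[k].update(v)
        else:
            raw[k] = v

    known = {
        "mechanics", "chain", "subdomains", "unbinding", "simulation",
        "analysis", "master_equation", "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    mech = _build(MechanicalParams, dict(raw.get("mechanics") or {}), "mechanics")
    chain = _build(ChainConfig, dict(raw.get("chain") or {}), "chain")
    unfold = _parse_unfold(raw.get("subdomains"), chain)
    unbind = _parse_unbind(dict(raw.get("unbinding") or {}))
    sim = _build(SimParams, dict(raw.get("simulation") or {}), "simulation")
    ana_raw = dict(raw.get("analysis") or {})
    if "flow_axis" in ana_raw:
        ana_raw["flow_axis"] = tuple(ana_raw["flow_axis"])
    ana = _build(AnalysisConfig, ana_raw, "analysis")
    me_raw = dict(raw.get("master_equation") or {})
    unknown_me = set(me_raw) - {"dt", "t_max", "p_terminate"}
    if unknown_me:
        raise ConfigError(f"master_equation: unknown key(s) {sorted(unknown_me)}")
    return RunConfig(
        mechanics=mech,
        chain=chain,
        unfold=unfold,
        unbind=unbind,
        simulation=sim,
        analysis=ana,
        dt_master=float(me_raw.get("dt", 1e-3)),
        t_max=float(me_raw.get("t_max", 600.0)),
        p_terminate=float(me_raw.get("p_terminate", 0.999)),
        seed=int(raw.get("seed", 0)),
    )
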