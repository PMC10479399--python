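"""High-level model objects tying the solvers and the track analysis together.

:class:`TalinChainModel` bundles one Talin linkage (mechanics, chain
composition, kinetics) and exposes the two solution methods --
``solve()`` for the deterministic master equation and ``simulate(n)``
for stochastic pulling ensembles -- each returning a result object with
the observables and a ``summary()``.

:class:`SpeckleKinetics` is the data-analysis counterpart: built from a
set of speckle tracks, ``fit()`` classifies them, runs the censored
survival analysis per transition and solves the flux balance, returning
a :class:`SpeckleKineticsResults` with the rate table and state
proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import master_equation as me
from . import pulling
from .config import AnalysisConfig
from .kinetics import BellParams, DEFAULT_UNBIND, DEFAULT_K_UNFOLD0, DEFAULT_DX_UNFOLD
from .mechanics import ChainConfig, MechanicalParams
from .sims import (
    COARSE_RATES,
    classify_tracks,
    clutch_flux_balance,
    km_exponential_rate,
)
from .synth import _segment_durations  # shared segment/censoring semantics

__all__ = ["TalinChainModel", "PullingEnsembleResult", "SpeckleKinetics", "SpeckleKineticsResults"]


class TalinChainModel:
    """One Talin linkage under retrograde-flow loading.

    Parameters default to the published chain mechanics (10 pN/nm folded
    springs, 2 nm rest length, 0.38 nm Kuhn length, 145 residues per
    subdomain, 300 K) with a 12-subdomain chain, the measured
    slip-bond unbinding (0.17 1/s, 0.51 nm) and illustrative unfolding
    parameters.
    """

    def __init__(
        self,
        config: ChainConfig | None = None,
        mech: MechanicalParams | None = None,
        unfold=None,
        unbind=DEFAULT_UNBIND,
    ) -> None:
        self.config = config or ChainConfig()
        self.mech = mech or MechanicalParams()
        self.unfold = unfold if unfold is not None else BellParams(
            DEFAULT_K_UNFOLD0, DEFAULT_DX_UNFOLD
        )
        self.unbind = unbind

    @classmethod
    def from_config(cls, run_config) -> "TalinChainModel":
        return cls(
            config=run_config.chain,
            mech=run_config.mechanics,
            unfold=run_config.unfold,
            unbind=run_config.unbind,
        )

    def solve(self, dt: float = 1e-3, t_max: float = 600.0, p_terminate: float = 0.999):
        """Master-equation solution (:class:`~.master_equation.MasterEqResult`)."""
        return me.solve(
            self.config, self.mech, self.unfold, self.unbind,
            dt=dt, t_max=t_max, p_terminate=p_terminate,
        )

    def simulate(
        self, n: int, seed: int = 0, sim: pulling.SimParams | None = None
    ) -> "PullingEnsembleResult":
        """Stochastic pulling ensemble of ``n`` traces."""
        sim = sim or pulling.SimParams()
        table = pulling.run_ensemble(
            self.config, self.mech, sim, self.unfold, self.unbind,
            n=n, base_seed=seed,
        )
        return PullingEnsembleResult(table=table, model=self, sim=sim, seed=seed)

    def sweep(self, vary: dict, **kwargs) -> pd.DataFrame:
        return me.sweep(self.config, self.mech, self.unfold, self.unbind, vary=vary, **kwargs)


@dataclass
class PullingEnsembleResult:
    """Per-trace table plus ensemble aggregates of a pulling run."""

    table: pd.DataFrame
    model: TalinChainModel
    sim: pulling.SimParams
    seed: int

    @property
    def mean_unbinding_time(self) -> float:
        return float(self.table["t_unbind_s"].mean())

    @property
    def sem_unbinding_time(self) -> float:
        return float(self.table["t_unbind_s"].sem())

    @property
    def mean_work(self) -> float:
        return float(self.table["work_pN_nm"].mean())

    @property
    def sem_work(self) -> float:
        return float(self.table["work_pN_nm"].sem())

    def summary(self) -> str:
        cfg = self.model.config
        t = self.table
        return "\n".join(
            [
                "Talin pulling ensemble",
                f"  N = {cfg.n_total}, M = {cfg.n_unfoldable}, "
                f"theta0 = {cfg.theta0:.1f} deg, v_retro = {cfg.v_retro:.1f} nm/s",
                f"  n = {len(t)}, dt = {self.sim.dt_sim:g} s, zeta = {self.sim.zeta:g} pN s/nm, "
                f"seed = {self.seed}",
                f"  mean unbinding time = {self.mean_unbinding_time:.3f} "
                f"+- {self.sem_unbinding_time:.3f} s",
                f"  mean work on actin  = {self.mean_work:.1f} +- {self.sem_work:.1f} pN nm",
                f"  mean unfold events  = {t['n_unfolds'].mean():.2f}",
                f"  censored traces     = {int(t['censored'].sum())}",
            ]
        )


class SpeckleKinetics:
    """Censored survival analysis of classified speckle tracks.

    ``window`` is the acquisition window (s) used to recognise
    right-censoring at the end of the recording.
    """

    def __init__(
        self,
        tracks,
        mode: str = "coarse_2s",
        window: float = 120.0,
        analysis: AnalysisConfig | None = None,
    ) -> None:
        self.tracks = list(tracks)
        self.mode = mode
        self.window = window
        self.analysis = analysis or AnalysisConfig(mode=mode)

    def fit(self) -> "SpeckleKineticsResults":
        labels = classify_tracks(
            self.tracks, mode=self.mode,
            motion_threshold=self.analysis.motion_threshold,
        )
        frame_interval = self.tracks[0].frame_interval if self.tracks else 2.0
        by_id = {tr.id: tr for tr in self.tracks}
        (stat_dur, stat_sw), (flow_dur, flow_sw) = _segment_durations(
            labels, by_id, self.window, frame_interval
        )
        bleach = self.analysis.bleach_per_frame
        rows = {}
        specs = {
            "k1": (stat_dur, stat_sw, False, bleach),
            "k2": (stat_dur, stat_sw, True, None),
            "k3": (flow_dur, flow_sw, False, bleach),
            "k4": (flow_dur, flow_sw, True, None),
        }
        for name, (durs, flags, switch_is_event, bl) in specs.items():
            if not durs:
                rows[name] = None
                continue
            if switch_is_event:
                cen = [f is not True for f in flags]
            else:
                cen = [f is not False for f in flags]
            try:
                rows[name] = km_exponential_rate(
                    durs, cen, bleach_per_frame=bl, frame_interval=frame_interval
                )
            except ValueError:
                rows[name] = None

        counts = pd.Series([l.category for l in labels]).value_counts().to_dict()
        # observation-weighted state fractions over classified tracks
        frames = {"stationary": 0, "flowing": 0}
        for lab in labels:
            if lab.category in ("excluded", "unclassified"):
                continue
            for a, b, mode_ in lab.segments:
                if mode_ in frames:
                    frames[mode_] += b - a
        tot = sum(frames.values()) or 1
        fractions = {k: v / tot for k, v in frames.items()}
        return SpeckleKineticsResults(
            labels=labels, rates=rows, category_counts=counts,
            state_fractions=fractions, mode=self.mode,
        )


@dataclass
class SpeckleKineticsResults:
    """Rates, classification tallies and state fractions of one fit."""

    labels: list
    rates: dict
    category_counts: dict
    state_fractions: dict
    mode: str

    def rate_table(self) -> pd.DataFrame:
        rows = []
        for name, est in self.rates.items():
            if est is None:
                continue
            rows.append(
                {
                    "rate": name,
                    "estimate_per_s": est.rate,
                    "mle_per_s": est.rate_mle,
                    "n_events": est.n_events,
                    "n_censored": est.n_censored,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "bleach_corrected": est.bleach_corrected,
                }
            )
        return pd.DataFrame(rows)

    def flux_balance(self, clutch_rates: dict, S_percent: float | None = None):
        """Solve the four-state flux balance using this fit's k2/k4 and
        the supplied clutch rates (k_a, k_b, k_c, k_d)."""
        if S_percent is None:
            S_percent = 100.0 * self.state_fractions.get("stationary", 0.57)
        k2 = self.rates["k2"].rate if self.rates.get("k2") else COARSE_RATES["k2"]
        k4 = self.rates["k4"].rate if self.rates.get("k4") else COARSE_RATES["k4"]
        return clutch_flux_balance(
            S_percent,
            {
                "k_a": clutch_rates["k_a"], "k_b": clutch_rates["k_b"],
                "k_c": clutch_rates["k_c"], "k_d": clutch_rates["k_d"],
                "k_2": k2, "k_4": k4,
            },
        )

    def summary(self) -> str:
        lines = [
            f"Speckle kinetics fit ({self.mode})",
            "  categories: "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.category_counts.items())),
            "  state fractions (frame-weighted): "
            + ", ".join(f"{k}={v:.3f}" for k, v in self.state_fractions.items()),
        ]
        for name, est in self.rates.items():
            if est is None:
                lines.append(f"  {name}: no events")
            else:
                lines.append(
                    f"  {name} = {est.rate:.4f} 1/s "
                    f"({est.n_events} events, {est.n_censored} censored"
                    + (", bleach-corrected" if est.bleach_corrected else "")
                    + ")"
                )
        return "\n".join(lines)
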