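"""Deterministic evolution of the Talin-linkage state probabilities.

The chain state is the set of unfolded rod subdomains; with identical
subdomain parameters only the number ``j`` of unfolded subdomains
matters (homogeneous path, states j = 0..M plus unbound), while
per-subdomain parameters require tracking all 2^M bit-states
(heterogeneous path).  Each discrete step evaluates the uniform tension
at the chain length imposed by the retrograde flow, converts Bell-law
rates to per-step probabilities 1 - exp(-k dt), redistributes bound
probability over additional unfolds with a binomial kernel, and removes
unbinding mass.  Unbinding-time/displacement densities, the
maximum-force histogram, the ensemble-average unbinding force and the
accumulated work on actin are derived from the recorded trajectories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .kinetics import BellParams, CatchSlipParams, SubdomainSpec, DEFAULT_UNBIND
from .mechanics import ChainConfig, MechanicalParams

__all__ = [
    "StepSizeError",
    "MasterEqResult",
    "UnbindingDistributions",
    "Observables",
    "step_probabilities",
    "unfold_transition_matrix",
    "solve",
    "observables",
    "sweep",
    "calibrate_dx_unbind",
]

_CHUNK = 20_000


class StepSizeError(RuntimeError):
    """The discrete time step produced probabilities outside [0, 1]."""


def step_probabilities(rates, dt: float):
    """Per-step event probabilities 1 - exp(-k dt), elementwise in [0, 1)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    out = -np.expm1(-rates * dt)
    return float(out) if out.ndim == 0 else out


def unfold_transition_matrix(M: int, i: int, p_unfold: float) -> np.ndarray:
    """Row i of the unfolding redistribution kernel A.

    A_ij is the binomial probability that j - i of the M - i still-folded
    subdomains unfold within the step, each independently with
    probability ``p_unfold``; the row sums to 1.
    """
    if not 0 <= i <= M:
        raise ValueError("need 0 <= i <= M")
    if not 0 <= p_unfold < 1:
        raise ValueError("need 0 <= p_unfold < 1")
    row = np.zeros(M + 1)
    for j in range(i, M + 1):
        row[j] = (
            math.comb(M - i, j - i)
            * (1.0 - p_unfold) ** (M - j)
            * p_unfold ** (j - i)
        )
    return row


@dataclass
class UnbindingDistributions:
    """Densities derived from dP_unbound/dt and the per-state tensions."""

    time_grid: np.ndarray           # s, step start times
    time_density: np.ndarray        # 1/s, unbinding-time density
    displacement_grid: np.ndarray   # nm, x = v t
    displacement_density: np.ndarray  # 1/nm
    fmax_edges: np.ndarray          # pN, histogram bin edges
    fmax_hist: np.ndarray           # probability mass per bin


@dataclass
class Observables:
    """Scalar observables + distributions of one master-equation run."""

    mean_clutch_duration: float     # s
    mean_work: float                # pN nm
    mean_unbind_displacement: float  # nm
    p_unbound_end: float
    work_trace: np.ndarray          # pN nm, cumulative W(t)
    mean_force_trace: np.ndarray    # pN, unbind-weighted mean force
    distributions: UnbindingDistributions
    partial: bool = False


@dataclass
class MasterEqResult:
    """Trajectory record of one master-equation run.

    ``P[n, j]`` and ``F[n, j]`` are the bound-state probability and
    tension of state j at the start of step n (heterogeneous runs are
    aggregated by unfolded-subdomain count); ``unbind_mass[n, j]`` is
    the probability mass unbinding from state j during step n.
    """

    t: np.ndarray
    P: np.ndarray
    F: np.ndarray
    unbind_mass: np.ndarray
    dt: float
    config: ChainConfig
    mech: MechanicalParams
    heterogeneous: bool
    terminated: bool

    @property
    def M(self) -> int:
        return self.P.shape[1] - 1

    @property
    def P_unbound(self) -> np.ndarray:
        """1 - sum_j P_j at the start of each step (non-decreasing)."""
        return 1.0 - self.P.sum(axis=1)

    def observables(self, fmax_bin_width: float = 0.5) -> Observables:
        return observables(self, self.config, fmax_bin_width=fmax_bin_width)

    def summary(self) -> str:
        obs = self.observables()
        cfg = self.config
        lines = [
            "Talin clutch master-equation run",
            f"  N = {cfg.n_total}, M = {self.M}, theta0 = {cfg.theta0:.1f} deg, "
            f"v_retro = {cfg.v_retro:.1f} nm/s",
            f"  path: {'heterogeneous' if self.heterogeneous else 'homogeneous'}, "
            f"dt = {self.dt:g} s, steps = {len(self.t)}",
            f"  P_unbound(end)        = {obs.p_unbound_end:.6f}"
            + ("" if self.terminated else "  [not converged]"),
            f"  mean clutch duration  = {obs.mean_clutch_duration:.4f} s",
            f"  mean work on actin    = {obs.mean_work:.3f} pN nm",
            f"  mean unbind displacement = {obs.mean_unbind_displacement:.2f} nm",
        ]
        return "\n".join(lines)


def _unbind_arrays(unbind):
    if isinstance(unbind, BellParams):
        return 0, np.array([unbind.k0, unbind.dx, 0, 0, 0, 0, 0, 0], dtype=float)
    if isinstance(unbind, CatchSlipParams):
        return 1, np.array(
            [
                unbind.k10_0, unbind.k12_0, unbind.k21_0, unbind.k20_0,
                unbind.x10, unbind.x20, unbind.x12, unbind.x21,
            ],
            dtype=float,
        )
    raise TypeError(f"unsupported unbinding model: {type(unbind).__name__}")


def solve(
    config: ChainConfig,
    mech: MechanicalParams,
    unfold,
    unbind=DEFAULT_UNBIND,
    dt: float = 1e-3,
    t_max: float = 600.0,
    p_terminate: float = 0.999,
) -> MasterEqResult:
    """Integrate the master equation until ``P_unbound > p_terminate``.

    ``unfold`` is either :class:`BellParams` (identical subdomains,
    homogeneous path over the count of unfolded subdomains) or a
    :class:`SubdomainSpec` (heterogeneous path over 2^M bit-states; the
    state space limits M to about 20, and runtime is practical for
    M <= ~12).  ``unbind`` is a slip :class:`BellParams` or a
    :class:`CatchSlipParams` bond.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    heterogeneous = isinstance(unfold, SubdomainSpec)
    if heterogeneous:
        if unfold.n_total != config.n_total:
            raise ValueError("SubdomainSpec length must equal config.n_total")
        k0_all, dx_all, unfoldable = unfold.arrays()
        M = int(unfoldable.sum())
        if M != config.n_unfoldable:
            raise ValueError("SubdomainSpec unfoldable count must equal n_unfoldable")
        if M > 20:
            raise ValueError("heterogeneous state space 2^M too large (M > 20)")
        ku0 = np.ascontiguousarray(k0_all[unfoldable])
        kdx = np.ascontiguousarray(dx_all[unfoldable])
    else:
        if not isinstance(unfold, BellParams):
            raise TypeError("unfold must be BellParams or SubdomainSpec")
        M = config.n_unfoldable

    ub_kind, ub_params = _unbind_arrays(unbind)
    L0 = config.rest_length(mech)
    costheta = math.cos(math.radians(config.theta0))
    args = (
        M, config.n_segments, L0, costheta, config.v_retro,
        mech.l_folded0, mech.k_folded_nm, mech.kuhn_b, float(mech.n_res), mech.kT,
    )

    P = np.zeros((1 << M) if heterogeneous else M + 1)
    P[0] = 1.0
    tau = np.zeros(M + 1)
    t_blocks, P_blocks, F_blocks, U_blocks = [], [], [], []
    step0 = 0
    terminated = False
    max_steps = int(round(t_max / dt))

    while step0 < max_steps:
        n = min(_CHUNK, max_steps - step0)
        P_out = np.empty((n, M + 1))
        F_out = np.empty((n, M + 1))
        U_out = np.empty((n, M + 1))
        if heterogeneous:
            done, P, tau = _kernels.run_me_heterogeneous(
                *args, ku0, kdx, ub_kind, ub_params,
                dt, n, step0, P, tau, P_out, F_out, U_out,
            )
        else:
            done, P, tau = _kernels.run_me_homogeneous(
                *args, unfold.k0, unfold.dx, ub_kind, ub_params,
                dt, n, step0, P, tau, P_out, F_out, U_out,
            )
        if np.min(P_out) < -1e-9:
            raise StepSizeError(
                f"bound-state probability went negative (min {np.min(P_out):.3e}); "
                f"reduce dt (currently {dt:g} s)"
            )
        t_blocks.append((step0 + np.arange(done)) * dt)
        P_blocks.append(P_out[:done])
        F_blocks.append(F_out[:done])
        U_blocks.append(U_out[:done])
        step0 += done
        if 1.0 - P.sum() > p_terminate:
            terminated = True
            break

    return MasterEqResult(
        t=np.concatenate(t_blocks),
        P=np.concatenate(P_blocks),
        F=np.concatenate(F_blocks),
        unbind_mass=np.concatenate(U_blocks),
        dt=dt,
        config=config,
        mech=mech,
        heterogeneous=heterogeneous,
        terminated=terminated,
    )


def observables(
    result: MasterEqResult,
    config: ChainConfig | None = None,
    fmax_bin_width: float = 0.5,
) -> Observables:
    """Observables of a run: mean clutch duration, work, distributions.

    The unbinding-time density is the per-step unbinding mass divided by
    dt; the displacement density follows from x = v t; work accumulates
    the flow-axis tension component times the flow displacement per step
    over the still-bound ensemble.
    """
    if config is None:
        config = result.config
    t = result.t
    dt = result.dt
    u = result.unbind_mass.sum(axis=1)        # mass unbinding in each step
    p_end = float(u.sum())
    partial = not result.terminated
    if partial:
        warnings.warn(
            f"run not converged (P_unbound(end) = {p_end:.4f}); "
            "observables are conditional on the observed window",
            stacklevel=2,
        )
    if p_end <= 0:
        raise ValueError("no unbinding mass accumulated; cannot form observables")

    # event times assigned to the end of the step in which they occur
    t_event = t + dt
    mean_duration = float((t_event * u).sum() / p_end)
    v = config.v_retro
    mean_displacement = v * mean_duration

    # geometry factor for the tension component along the flow axis
    L0 = config.rest_length(result.mech)
    c0 = math.cos(math.radians(config.theta0))
    L = np.sqrt(L0**2 + 2 * L0 * v * t * c0 + (v * t) ** 2)
    cosphi = (L0 * c0 + v * t) / L
    work_steps = (result.F * result.P).sum(axis=1) * cosphi * v * dt
    work_trace = np.cumsum(work_steps)
    mean_work = float(work_trace[-1])

    # Eq-17-style unbind-weighted mean force at each time
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_force = (result.F * result.unbind_mass).sum(axis=1) / u
    mean_force = np.where(u > 0, mean_force, 0.0)

    fmax = result.F.ravel()
    w = result.unbind_mass.ravel()
    f_hi = max(fmax_bin_width, float(fmax[w > 0].max()) if np.any(w > 0) else 1.0)
    edges = np.arange(0.0, f_hi + 2 * fmax_bin_width, fmax_bin_width)
    hist, _ = np.histogram(fmax, bins=edges, weights=w)

    dist = UnbindingDistributions(
        time_grid=t_event,
        time_density=u / dt,
        displacement_grid=v * t_event,
        displacement_density=(u / (v * dt)) if v > 0 else np.zeros_like(u),
        fmax_edges=edges,
        fmax_hist=hist,
    )
    return Observables(
        mean_clutch_duration=mean_duration,
        mean_work=mean_work,
        mean_unbind_displacement=mean_displacement,
        p_unbound_end=p_end,
        work_trace=work_trace,
        mean_force_trace=mean_force,
        distributions=dist,
        partial=partial,
    )


def sweep(
    config: ChainConfig,
    mech: MechanicalParams,
    unfold,
    unbind=DEFAULT_UNBIND,
    vary: dict | None = None,
    dt: float = 1e-3,
    t_max: float = 600.0,
    p_terminate: float = 0.999,
) -> pd.DataFrame:
    """Grid sweep over chain-configuration fields (full cartesian product).

    ``vary`` maps ChainConfig field names (``n_total``, ``n_unfoldable``,
    ``theta0``, ``v_retro``) to value sequences.  Returns one row of
    observables per grid point; deterministic given the configuration.
    """
    vary = dict(vary or {})
    allowed = {"n_total", "n_unfoldable", "theta0", "v_retro"}
    bad = set(vary) - allowed
    if bad:
        raise ValueError(f"cannot sweep over {sorted(bad)}; allowed: {sorted(allowed)}")
    keys = list(vary)
    grids = [list(vary[k]) for k in keys]

    rows = []
    for point in _product(grids):
        overrides = dict(zip(keys, point))
        cfg_kwargs = {
            "n_total": config.n_total,
            "n_unfoldable": config.n_unfoldable,
            "theta0": config.theta0,
            "v_retro": config.v_retro,
        }
        cfg_kwargs.update(overrides)
        if "n_total" in overrides and "n_unfoldable" not in overrides:
            cfg_kwargs["n_unfoldable"] = min(
                cfg_kwargs["n_unfoldable"], cfg_kwargs["n_total"]
            )
        cfg = ChainConfig(**cfg_kwargs)
        unf = unfold
        if isinstance(unfold, SubdomainSpec) and (
            unfold.n_total != cfg.n_total or unfold.n_unfoldable != cfg.n_unfoldable
        ):
            raise ValueError(
                "sweeping chain composition with a per-subdomain SubdomainSpec "
                "is ambiguous; pass BellParams instead"
            )
        res = solve(cfg, mech, unf, unbind, dt=dt, t_max=t_max, p_terminate=p_terminate)
        obs = res.observables()
        rows.append(
            {
                **cfg_kwargs,
                "mean_clutch_duration_s": obs.mean_clutch_duration,
                "mean_work_pN_nm": obs.mean_work,
                "mean_unbind_displacement_nm": obs.mean_unbind_displacement,
                "p_unbound_end": obs.p_unbound_end,
            }
        )
    return pd.DataFrame(rows)


def _product(grids):
    if not grids:
        yield ()
        return
    head, *tail = grids
    for h in head:
        for rest in _product(tail):
            yield (h, *rest)


def calibrate_dx_unbind(
    target_edges: np.ndarray,
    target_counts: np.ndarray,
    grid: Sequence[float],
    config: ChainConfig,
    mech: MechanicalParams,
    unfold,
    k_unbind0: float = DEFAULT_UNBIND.k0,
    dt: float = 1e-3,
    t_max: float = 600.0,
    p_terminate: float = 0.999,
):
    """Pick the unbinding barrier distance that best matches a measured
    unbinding-displacement histogram.

    For each candidate dx on ``grid`` the master equation is solved and
    its displacement density is binned onto the target's bin edges; the
    returned value minimises the chi-square discrepancy between the two
    normalised histograms over the shared bins.  Near-degenerate optima
    (within 1e-12) trigger an ambiguity warning listing the ties.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty search grid")
    if np.any((grid <= 0) | (grid > 5)):
        raise ValueError("grid values must lie in (0, 5] nm")
    target_counts = np.asarray(target_counts, dtype=float)
    target_edges = np.asarray(target_edges, dtype=float)
    if target_counts.sum() <= 0:
        raise ValueError("target histogram is empty")
    q = target_counts / target_counts.sum()

    scores = np.empty(grid.size)
    for g, dx in enumerate(grid):
        res = solve(
            config, mech, unfold, BellParams(k_unbind0, float(dx)),
            dt=dt, t_max=t_max, p_terminate=p_terminate,
        )
        obs = res.observables()
        d = obs.distributions
        mass, _ = np.histogram(
            d.displacement_grid, bins=target_edges,
            weights=d.time_density * res.dt,
        )
        total = mass.sum()
        if total <= 0:
            scores[g] = np.inf
            continue
        p = mass / total
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(p > 0, (q - p) ** 2 / p, np.where(q > 0, np.inf, 0.0))
        scores[g] = chi2.sum()

    best = int(np.argmin(scores))
    ties = grid[np.abs(scores - scores[best]) <= 1e-12]
    if ties.size > 1:
        warnings.warn(
            f"calibration objective is flat; tied grid values: {ties.tolist()}",
            stacklevel=2,
        )
    return float(grid[best]), pd.DataFrame({"dx_unbind_nm": grid, "chi2": scores})
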