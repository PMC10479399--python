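"""Explicit stochastic bead--spring realisations of the Talin linkage.

Each trace integrates the overdamped bead equations of motion
(forward Euler) while the actin-side anchor is dragged at the
retrograde-flow speed, and draws unfolding/unbinding events by Monte
Carlo from the local segment tension.  Thermal motion of the beads is
not simulated explicitly: fluctuations enter through Bell's law and the
entropic FJC elasticity, as in the master-equation path.

The chain is N+3 beads: an integrin anchor (fixed), N+1 chain beads
bounding the N rod subdomains, and an actin bead (driven).  The
compliance variant appends a substrate bead behind the integrin anchor
and an actin-network bead beyond the actin bead, joined by Hookean
springs of constant k3; then only the substrate bead is stationary and
the network bead carries the drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .kinetics import (
    BellParams,
    SubdomainSpec,
    DEFAULT_UNBIND,
    DEFAULT_K_UNFOLD0,
    DEFAULT_DX_UNFOLD,
    bell_rate,
    unbind_rate,
)
from .master_equation import _unbind_arrays
from .mechanics import ChainConfig, MechanicalParams, inverse_langevin

__all__ = [
    "SimParams",
    "PullingTrace",
    "ChainState",
    "init_chain",
    "step",
    "run_single",
    "run_ensemble",
]


class SimulationInstabilityError(RuntimeError):
    """A bead moved more than 1 nm in a single step."""


@dataclass(frozen=True)
class SimParams:
    """Numerical parameters of the pulling simulation.

    ``zeta`` (pN s/nm) sets the bead relaxation time zeta/k_folded;
    the default pairing (1e-4, 1e-6 s) keeps the integration stable
    while relaxing tension much faster than any kinetic timescale.
    ``compliance_k3`` (pN/µm), if set, activates the soft-anchor
    variant.
    """

    zeta: float = 1e-4
    dt_sim: float = 1e-6
    seed: int = 0
    n_realizations: int = 1
    compliance_k3: float | None = None
    t_max: float = 600.0

    def __post_init__(self) -> None:
        if self.zeta <= 0 or self.dt_sim <= 0:
            raise ValueError("zeta and dt_sim must be positive")
        if self.compliance_k3 is not None and self.compliance_k3 <= 0:
            raise ValueError("compliance_k3 must be positive when set")

    def check_stability(self, mech: MechanicalParams) -> None:
        k_max = mech.k_folded_nm
        if self.compliance_k3 is not None:
            k_max = max(k_max, self.compliance_k3 / 1000.0)
        if self.dt_sim * k_max / self.zeta >= 0.5:
            raise ValueError(
                f"unstable parameters: dt_sim * k / zeta = "
                f"{self.dt_sim * k_max / self.zeta:.3f} >= 0.5"
            )


@dataclass
class PullingTrace:
    """One stochastic realisation: event log and terminal quantities."""

    seed: int
    unbinding_time: float           # s (censoring time if censored)
    work: float                     # pN nm
    n_unfolds: int
    event_times: np.ndarray         # s, unfold events (strictly increasing)
    event_segments: np.ndarray      # rod segment index per unfold
    event_tensions: np.ndarray      # pN, local tension at the event
    censored: bool
    final_positions: np.ndarray     # (n_beads, 2) nm


@dataclass
class ChainState:
    """Mutable bead/segment state for the Python-level stepper."""

    positions: np.ndarray           # (n_beads, 2) nm
    seg_unfolded: np.ndarray        # bool per segment
    seg_k: np.ndarray               # pN/nm for Hookean segments
    seg_rest: np.ndarray            # nm
    seg_is_rod: np.ndarray
    seg_unfoldable: np.ndarray
    fixed_idx: int
    driven_idx: int
    unbind_seg: int
    t: float = 0.0
    work: float = 0.0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def segment_tensions(self, mech: MechanicalParams) -> np.ndarray:
        d = np.diff(self.positions, axis=0)
        r = np.hypot(d[:, 0], d[:, 1])
        tau = np.zeros_like(r)
        folded = ~self.seg_unfolded
        ext = r[folded] - self.seg_rest[folded]
        tau[folded] = self.seg_k[folded] * np.clip(ext, 0.0, None)
        if np.any(self.seg_unfolded):
            x = np.clip(r[self.seg_unfolded] / mech.contour_length, 0.0, 0.999999)
            tau[self.seg_unfolded] = (mech.kT / mech.kuhn_b) * inverse_langevin(x)
        return tau

    def elastic_energy(self, mech: MechanicalParams) -> float:
        """Stored elastic energy, pN nm (Hookean 1/2 k ext^2; FJC free
        energy n kT [X y - log(sinh y / y)] with y = L^-1(X))."""
        d = np.diff(self.positions, axis=0)
        r = np.hypot(d[:, 0], d[:, 1])
        e = 0.0
        for s in range(r.size):
            if self.seg_unfolded[s]:
                X = min(r[s] / mech.contour_length, 0.999999)
                if X > 0:
                    y = inverse_langevin(X)
                    e += mech.kT * mech.n_res * (X * y - math.log(math.sinh(y) / y))
            else:
                ext = r[s] - self.seg_rest[s]
                if ext > 0:
                    e += 0.5 * self.seg_k[s] * ext * ext
        return e


def _build_segments(
    config: ChainConfig, mech: MechanicalParams, sim: SimParams,
    unfold_spec: SubdomainSpec | None = None,
):
    N = config.n_total
    compliance = sim.compliance_k3 is not None
    n_beads = N + 3 + (2 if compliance else 0)
    n_segs = n_beads - 1

    seg_k = np.full(n_segs, mech.k_folded_nm)
    seg_rest = np.full(n_segs, mech.l_folded0)
    seg_is_rod = np.zeros(n_segs, dtype=bool)
    seg_unfoldable = np.zeros(n_segs, dtype=bool)
    seg_ku0 = np.zeros(n_segs)
    seg_kdx = np.zeros(n_segs)

    rod0 = 2 if compliance else 1  # first rod segment index
    if unfold_spec is None:
        unfold_spec = SubdomainSpec.uniform(N, config.n_unfoldable)
    k0, dx, unf = unfold_spec.arrays()
    for j in range(N):
        s = rod0 + j
        seg_is_rod[s] = True
        seg_unfoldable[s] = unf[j]
        seg_ku0[s] = k0[j]
        seg_kdx[s] = dx[j]

    if compliance:
        k3_nm = sim.compliance_k3 / 1000.0
        seg_k[0] = k3_nm
        seg_k[-1] = k3_nm
        fixed_idx, driven_idx = 0, n_beads - 1
        unbind_seg = 1
    else:
        fixed_idx, driven_idx = 0, n_beads - 1
        unbind_seg = 0
    return (
        seg_k, seg_rest, seg_is_rod, seg_unfoldable, seg_ku0, seg_kdx,
        fixed_idx, driven_idx, unbind_seg,
    )


def init_chain(
    config: ChainConfig, mech: MechanicalParams, sim: SimParams
) -> np.ndarray:
    """Initial bead positions: all segments at rest length, collinear at
    ``theta0`` to the substrate (x = flow axis), integrin anchor at the
    origin.  The compliance variant adds one bead at each end."""
    compliance = sim.compliance_k3 is not None
    n_beads = config.n_total + 3 + (2 if compliance else 0)
    th = math.radians(config.theta0)
    u = np.array([math.cos(th), math.sin(th)])
    start = -u * mech.l_folded0 if compliance else np.zeros(2)
    pos = start[None, :] + np.arange(n_beads)[:, None] * u[None, :] * mech.l_folded0
    return pos


def make_state(
    config: ChainConfig, mech: MechanicalParams, sim: SimParams,
    unfold_spec: SubdomainSpec | None = None,
) -> ChainState:
    """Assemble a :class:`ChainState` ready for stepping."""
    (
        seg_k, seg_rest, seg_is_rod, seg_unfoldable, _ku0, _kdx,
        fixed_idx, driven_idx, unbind_seg,
    ) = _build_segments(config, mech, sim, unfold_spec)
    return ChainState(
        positions=init_chain(config, mech, sim),
        seg_unfolded=np.zeros(seg_k.size, dtype=bool),
        seg_k=seg_k,
        seg_rest=seg_rest,
        seg_is_rod=seg_is_rod,
        seg_unfoldable=seg_unfoldable,
        fixed_idx=fixed_idx,
        driven_idx=driven_idx,
        unbind_seg=unbind_seg,
    )


def step(
    state: ChainState,
    config: ChainConfig,
    mech: MechanicalParams,
    sim: SimParams,
    rng: np.random.Generator | None = None,
    unfold_params: BellParams | None = None,
    unbind=DEFAULT_UNBIND,
) -> dict:
    """Advance the chain one timestep (reference Python implementation).

    Deterministic mechanics unless ``rng`` is given, in which case
    unfolding/unbinding events are drawn with per-step probability
    1 - exp(-k dt) from the local segment tension.  Returns a dict with
    the segment tensions and any events; raises on instability.
    Ensemble work should use :func:`run_single`/:func:`run_ensemble`,
    which run the compiled kernel.
    """
    dt = sim.dt_sim
    pos = state.positions
    tau = state.segment_tensions(mech)
    d = np.diff(pos, axis=0)
    r = np.hypot(d[:, 0], d[:, 1])
    with np.errstate(invalid="ignore"):
        unit = np.where(r[:, None] > 1e-12, d / np.maximum(r, 1e-12)[:, None], 0.0)
    f_seg = tau[:, None] * unit
    frc = np.zeros_like(pos)
    frc[:-1] += f_seg
    frc[1:] -= f_seg

    disp = frc * (dt / sim.zeta)
    disp[state.fixed_idx] = 0.0
    disp[state.driven_idx] = 0.0
    if np.any(np.hypot(disp[:, 0], disp[:, 1]) > 1.0):
        worst = float(np.hypot(disp[:, 0], disp[:, 1]).max())
        raise SimulationInstabilityError(
            f"bead displacement {worst:.2f} nm in one step at t={state.t:.3e} s; "
            f"dt_sim*k/zeta = {dt * state.seg_k.max() / sim.zeta:.3f}"
        )
    pos += disp
    pos[state.driven_idx, 0] += config.v_retro * dt
    state.t += dt

    ds = pos[state.driven_idx] - pos[state.driven_idx - 1]
    rs = math.hypot(ds[0], ds[1])
    if rs > 1e-12:
        state.work += tau[-1] * (ds[0] / rs) * config.v_retro * dt

    events = {"unfolded": [], "unbound": False, "tensions": tau}
    if rng is not None:
        if unfold_params is None:
            unfold_params = BellParams(DEFAULT_K_UNFOLD0, DEFAULT_DX_UNFOLD)
        eligible = state.seg_is_rod & state.seg_unfoldable & ~state.seg_unfolded
        for s in np.flatnonzero(eligible):
            k = bell_rate(tau[s], unfold_params, mech.kT)
            if rng.random() < -np.expm1(-k * dt):
                state.seg_unfolded[s] = True
                events["unfolded"].append(int(s))
        k_ub = unbind_rate(tau[state.unbind_seg], unbind, mech.kT)
        if rng.random() < -np.expm1(-k_ub * dt):
            events["unbound"] = True
    return events


def run_single(
    config: ChainConfig,
    mech: MechanicalParams,
    sim: SimParams,
    unfold=None,
    unbind=DEFAULT_UNBIND,
    seed: int | None = None,
) -> PullingTrace:
    """Run one pulling trace to unbinding (or censoring at ``sim.t_max``).

    ``unfold`` may be :class:`BellParams` (uniform subdomains) or a
    :class:`SubdomainSpec`; reproducible given ``seed``.
    """
    sim.check_stability(mech)
    if seed is None:
        seed = sim.seed
    if isinstance(unfold, BellParams):
        unfold = SubdomainSpec.uniform(
            config.n_total, config.n_unfoldable, unfold.k0, unfold.dx
        )
    (
        seg_k, seg_rest, seg_is_rod, seg_unfoldable, seg_ku0, seg_kdx,
        fixed_idx, driven_idx, unbind_seg,
    ) = _build_segments(config, mech, sim, unfold)
    ub_kind, ub_params = _unbind_arrays(unbind)
    pos0 = init_chain(config, mech, sim)

    status, t_end, work, n_ev, ev_t, ev_s, ev_f, pos = _kernels.run_pulling(
        pos0, fixed_idx, driven_idx,
        seg_k, seg_rest, seg_is_rod, np.zeros(seg_k.size, dtype=np.bool_),
        seg_ku0, seg_kdx, seg_unfoldable,
        unbind_seg, ub_kind, ub_params,
        mech.l_folded0, mech.k_folded_nm, mech.kuhn_b, float(mech.n_res), mech.kT,
        sim.zeta, sim.dt_sim, config.v_retro, sim.t_max, int(seed) & 0x7FFFFFFF,
    )
    if status == 2:
        raise SimulationInstabilityError(
            f"bead displacement exceeded 1 nm in one step at t={t_end:.3e} s "
            f"(seed {seed}); reduce dt_sim or increase zeta"
        )
    return PullingTrace(
        seed=int(seed),
        unbinding_time=float(t_end),
        work=float(work),
        n_unfolds=int(n_ev),
        event_times=np.asarray(ev_t),
        event_segments=np.asarray(ev_s),
        event_tensions=np.asarray(ev_f),
        censored=status == 1,
        final_positions=np.asarray(pos),
    )


def run_ensemble(
    config: ChainConfig,
    mech: MechanicalParams,
    sim: SimParams,
    unfold=None,
    unbind=DEFAULT_UNBIND,
    n: int | None = None,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Run ``n`` independent traces; returns a per-trace summary table.

    Columns: seed, t_unbind_s, work_pN_nm, n_unfolds, censored.  Trace
    seeds are ``base_seed + 1..n``.  Aggregate with ``.mean()`` /
    ``.sem()``; the distributions use the same binning conventions as
    the master-equation observables, so the two methods can be compared
    directly.
    """
    if n is None:
        n = sim.n_realizations
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_seed is None:
        base_seed = sim.seed
    rows = []
    for i in range(n):
        tr = run_single(config, mech, sim, unfold, unbind, seed=base_seed + 1 + i)
        rows.append(
            {
                "seed": tr.seed,
                "t_unbind_s": tr.unbinding_time,
                "work_pN_nm": tr.work,
                "n_unfolds": tr.n_unfolds,
                "censored": tr.censored,
            }
        )
    return pd.DataFrame(rows)
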