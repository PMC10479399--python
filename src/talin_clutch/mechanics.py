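"""Force laws and geometry of the Talin bead--spring chain.

The Talin rod is modeled as N rod subdomains in series plus two end
linkers (integrin bond and actin bond).  Folded subdomains and the two
end linkers are Hookean springs; unfolded subdomains are freely jointed
chains (FJC) whose force--extension relation involves the inverse
Langevin function.  All forces are tensile only: a segment shorter than
its rest length carries zero force, since the loading protocol (uniform
retrograde flow pulling one anchor) only ever lengthens the chain.

Internal units: pN, nm, s.  ``k_folded`` is accepted in pN/µm (the unit
the parameter is usually quoted in) and converted to pN/nm internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "MechanicalParams",
    "ChainConfig",
    "ChainMechanicalState",
    "langevin",
    "inverse_langevin",
    "folded_force",
    "unfolded_force",
    "fjc_extension",
    "total_length",
    "flow_direction_cosine",
    "solve_tension",
]

#: Boltzmann constant in pN nm / K (1.380649e-23 J/K = 1.380649e-2 pN nm/K).
BOLTZMANN_PN_NM_PER_K = 1.380649e-2


@dataclass(frozen=True)
class MechanicalParams:
    """Elastic parameters of one Talin linkage.

    Parameters
    ----------
    k_folded : float
        Spring constant of a folded rod subdomain and of the two end
        linkers, in pN/µm.  Default 1e4 pN/µm (10 pN/nm), typical of a
        globular rod subdomain.
    l_folded0 : float
        Rest length of a folded segment, nm.
    kuhn_b : float
        Kuhn length of the unfolded polypeptide, nm (one amino acid).
    n_res : int
        Number of amino acids per rod subdomain.
    temperature : float
        Absolute temperature, K.
    """

    k_folded: float = 1.0e4
    l_folded0: float = 2.0
    kuhn_b: float = 0.38
    n_res: int = 145
    temperature: float = 300.0

    def __post_init__(self) -> None:
        for name in ("k_folded", "l_folded0", "kuhn_b", "n_res", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.contour_length <= self.l_folded0:
            raise ValueError(
                "contour length per unfolded subdomain (kuhn_b * n_res) must "
                "exceed the folded rest length"
            )

    @property
    def kT(self) -> float:
        """Thermal energy k_B T in pN nm (4.1419 pN nm at 300 K)."""
        return BOLTZMANN_PN_NM_PER_K * self.temperature

    @property
    def k_folded_nm(self) -> float:
        """Folded spring constant in pN/nm."""
        return self.k_folded / 1000.0

    @property
    def contour_length(self) -> float:
        """Contour length of one unfolded subdomain, nm (b * n_res)."""
        return self.kuhn_b * self.n_res


@dataclass(frozen=True)
class ChainConfig:
    """Geometry and composition of one Talin linkage.

    ``n_total`` rod subdomains of which ``n_unfoldable`` may unfold; the
    two end linkers are always folded.  The chain starts straight at
    angle ``theta0`` (degrees) to the substrate and its actin anchor is
    dragged at ``v_retro`` (nm/s) in the flow direction.
    """

    n_total: int = 12
    n_unfoldable: int | None = None
    theta0: float = 45.0
    v_retro: float = 20.0

    def __post_init__(self) -> None:
        if self.n_unfoldable is None:
            object.__setattr__(self, "n_unfoldable", self.n_total)
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if not 0 <= self.n_unfoldable <= self.n_total:
            raise ValueError("need 0 <= n_unfoldable <= n_total")
        if not 0 < self.theta0 <= 90:
            raise ValueError("theta0 must be in (0, 90] degrees")
        if self.v_retro < 0:
            raise ValueError("v_retro must be >= 0")

    @property
    def n_segments(self) -> int:
        """Number of spring segments: N rod subdomains + 2 end linkers."""
        return self.n_total + 2

    def rest_length(self, params: MechanicalParams) -> float:
        """Initial (all-folded, relaxed) chain length L0 = (N+2) l_f0, nm."""
        return self.n_segments * params.l_folded0


@dataclass(frozen=True)
class ChainMechanicalState:
    """Uniform-tension solution for a chain of given total length."""

    n_unfolded: int
    tension: float          # pN
    l_folded: float         # nm, per folded segment
    l_unfolded: float       # nm, per unfolded segment
    L_tot: float            # nm


def langevin(y):
    """Langevin function L(y) = coth(y) - 1/y, series-stabilised near 0."""
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    small = np.abs(y) < 1e-4
    ys = y[small]
    out[small] = ys / 3.0 - ys**3 / 45.0
    yl = y[~small]
    out[~small] = 1.0 / np.tanh(yl) - 1.0 / yl
    return out if out.ndim else float(out)


def inverse_langevin(x, rtol: float = 1e-10, max_iter: int = 50):
    """Inverse Langevin function, y such that coth(y) - 1/y = x.

    Newton iteration seeded by the Cohen Padé approximant
    ``y0 = x (3 - x^2) / (1 - x^2)``.  Accepts scalars or arrays with
    0 <= x < 1; converges to relative tolerance well below 1e-8.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any((x_arr < 0) | (x_arr >= 1)):
        raise ValueError("inverse_langevin requires 0 <= x < 1")
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)

    y = x_arr * (3.0 - x_arr**2) / (1.0 - x_arr**2)
    nz = x_arr > 1e-6  # below this the Pade seed is exact to ~1e-13 relative
    for _ in range(max_iter):
        yn = y[nz]
        # f(y) = L(y) - x ; f'(y) = 1/y^2 - csch^2(y), series-stabilised
        with np.errstate(over="ignore"):
            csch2 = 1.0 / np.sinh(np.minimum(yn, 350.0)) ** 2
        f = langevin(yn) - x_arr[nz]
        fp = np.where(
            np.abs(yn) < 1e-4, 1.0 / 3.0 - yn**2 / 15.0, 1.0 / yn**2 - csch2
        )
        step = f / fp
        yn_new = yn - step
        # keep iterates in the domain
        yn_new = np.where(yn_new <= 0, yn / 2.0, yn_new)
        y[nz] = yn_new
        if np.all(np.abs(step) <= rtol * np.maximum(yn_new, 1e-300)):
            break
    return float(y[0]) if scalar else y


def folded_force(l, params: MechanicalParams):
    """Hookean tension of a folded segment of length ``l`` nm, in pN.

    Zero below the rest length (no compression)."""
    l = np.asarray(l, dtype=float)
    f = params.k_folded_nm * np.clip(l - params.l_folded0, 0.0, None)
    return float(f) if f.ndim == 0 else f


def unfolded_force(l, params: MechanicalParams):
    """FJC tension (kT/b) L^-1(l / (b n)) of an unfolded segment, pN.

    Diverges as ``l`` approaches the contour length b*n."""
    l_arr = np.asarray(l, dtype=float)
    if np.any((l_arr < 0) | (l_arr >= params.contour_length)):
        raise ValueError("unfolded segment length must lie in [0, contour length)")
    f = (params.kT / params.kuhn_b) * inverse_langevin(l_arr / params.contour_length)
    return float(f) if np.ndim(f) == 0 else f


def fjc_extension(tension, params: MechanicalParams):
    """Mean FJC end-to-end extension at a given tension (inverse of
    :func:`unfolded_force`): b n L(F b / kT), nm."""
    t = np.asarray(tension, dtype=float)
    if np.any(t < 0):
        raise ValueError("tension must be >= 0")
    x = params.contour_length * langevin(t * params.kuhn_b / params.kT)
    return float(x) if np.ndim(x) == 0 else x


def total_length(t, config: ChainConfig, params: MechanicalParams):
    """Anchor-to-anchor distance at time ``t`` under retrograde-flow loading.

    L(t) = sqrt(L0^2 + 2 L0 v t cos(theta0) + v^2 t^2) with
    L0 = (N+2) l_f0; non-decreasing for theta0 <= 90 deg.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    L0 = config.rest_length(params)
    v = config.v_retro
    c = math.cos(math.radians(config.theta0))
    L = np.sqrt(L0**2 + 2.0 * L0 * v * t * c + (v * t) ** 2)
    return float(L) if L.ndim == 0 else L


def flow_direction_cosine(t, config: ChainConfig, params: MechanicalParams):
    """Cosine of the angle between the chain axis and the flow direction.

    (L0 cos(theta0) + v t) / L(t); in (0, 1], tending to 1 as the chain
    is dragged flat.  This projects the uniform tension onto the flow
    axis for the work integral.
    """
    t = np.asarray(t, dtype=float)
    L0 = config.rest_length(params)
    c = math.cos(math.radians(config.theta0))
    out = (L0 * c + config.v_retro * t) / total_length(t, config, params)
    return float(out) if np.ndim(out) == 0 else out


class TensionSolverError(RuntimeError):
    """Raised when the 1-D tension root solve fails to converge."""


def _chain_length_at_tension(
    tau: float, i: int, n_seg: int, params: MechanicalParams
) -> float:
    l_f = params.l_folded0 + tau / params.k_folded_nm
    l_u = params.contour_length * langevin(tau * params.kuhn_b / params.kT)
    return i * l_u + (n_seg - i) * l_f


def solve_tension(
    L_tot: float,
    n_unfolded: int,
    config: ChainConfig,
    params: MechanicalParams,
    tol: float = 1e-9,
) -> ChainMechanicalState:
    """Uniform-tension force balance for ``n_unfolded`` unfolded segments.

    Solves L_tot = i l_u(tau) + (N+2-i) l_f(tau) with F_folded(l_f) =
    F_unfolded(l_u) = tau.  The left-hand side is strictly increasing in
    tau, so this is a monotone scalar root problem.  A slack chain
    (L_tot at or below the rest configuration) carries zero tension.
    """
    i = int(n_unfolded)
    if not 0 <= i <= config.n_total:
        raise ValueError("n_unfolded out of range")
    if L_tot <= 0:
        raise ValueError("L_tot must be positive")
    n_seg = config.n_segments

    if i == 0:
        # closed Hookean form: all segments share L_tot/(N+2)
        l = L_tot / n_seg
        tau = params.k_folded_nm * max(l - params.l_folded0, 0.0)
        l_f = params.l_folded0 + tau / params.k_folded_nm if tau > 0 else l
        return ChainMechanicalState(0, tau, l_f, 0.0, L_tot)

    rest = (n_seg - i) * params.l_folded0  # unfolded segments rest at zero extension
    if L_tot <= rest:
        return ChainMechanicalState(i, 0.0, L_tot / (n_seg - i), 0.0, L_tot)

    def f(tau: float) -> float:
        return _chain_length_at_tension(tau, i, n_seg, params) - L_tot

    hi = 1.0
    for _ in range(200):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise TensionSolverError(
            f"failed to bracket tension for L_tot={L_tot} nm, i={i}"
        )
    try:
        tau = brentq(f, 0.0, hi, xtol=1e-13, rtol=8.9e-16, maxiter=200)
    except RuntimeError as exc:  # pragma: no cover - scipy gives up
        raise TensionSolverError(
            f"tension solve did not converge (L_tot={L_tot}, i={i}): {exc}"
        ) from exc

    l_f = params.l_folded0 + tau / params.k_folded_nm
    l_u = params.contour_length * langevin(tau * params.kuhn_b / params.kT)
    residual = abs(i * l_u + (n_seg - i) * l_f - L_tot)
    if residual > max(tol, 1e-6):
        raise TensionSolverError(
            f"length conservation residual {residual:.2e} nm exceeds tolerance"
        )
    return ChainMechanicalState(i, tau, l_f, l_u, L_tot)
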