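"""Force-dependent rate laws for subdomain unfolding and integrin unbinding.

Two bond models are provided:

* a slip bond obeying Bell's law, k(F) = k0 exp(F dx / kT);
* a two-bound-state catch--slip bond in rapid equilibrium between a
  fast-dissociating state (1) and a slow-dissociating state (2), with
  force biasing the bond toward the slow state.  Its overall
  dissociation rate is (k21 k10 + k12 k20) / (k12 + k21), every k_ij
  itself Bell-like.

Unfolding parameters for the Talin rod subdomains are configurable per
subdomain; the shipped defaults (k_unfold0 = 1e-4 1/s, dx_unfold = 4 nm)
are an illustrative set in the range reported for Talin rod subdomains
in single-molecule experiments, not a fitted ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_K_UNFOLD0",
    "DEFAULT_DX_UNFOLD",
    "BellParams",
    "SubdomainSpec",
    "CatchSlipParams",
    "bell_rate",
    "catch_slip_unbind_rate",
]

#: Illustrative default zero-force unfolding rate, 1/s (configurable).
DEFAULT_K_UNFOLD0 = 1.0e-4
#: Illustrative default unfolding barrier distance, nm (configurable).
DEFAULT_DX_UNFOLD = 4.0

#: Cap on Bell exponents; beyond this exp() would overflow anyway and the
#: event is certain on any simulated timestep.
_EXP_CAP = 700.0


@dataclass(frozen=True)
class BellParams:
    """Zero-force rate k0 (1/s) and barrier distance dx (nm) of Bell's law."""

    k0: float
    dx: float

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be strictly positive")


#: Default slip-bond parameters of the Talin-integrin bond (measured).
DEFAULT_UNBIND = BellParams(k0=0.17, dx=0.51)


@dataclass(frozen=True)
class SubdomainSpec:
    """Per-subdomain unfolding parameters for the N rod subdomains.

    ``params[j]`` applies to rod subdomain j; ``unfoldable[j]`` marks the
    M subdomains allowed to unfold.
    """

    params: tuple
    unfoldable: tuple

    def __post_init__(self) -> None:
        if len(self.params) != len(self.unfoldable):
            raise ValueError("params and unfoldable must have equal length")

    @classmethod
    def uniform(
        cls,
        n_total: int,
        n_unfoldable: int,
        k0: float = DEFAULT_K_UNFOLD0,
        dx: float = DEFAULT_DX_UNFOLD,
    ) -> "SubdomainSpec":
        """All subdomains identical; the first ``n_unfoldable`` may unfold."""
        if not 0 <= n_unfoldable <= n_total:
            raise ValueError("need 0 <= n_unfoldable <= n_total")
        return cls(
            params=tuple(BellParams(k0, dx) for _ in range(n_total)),
            unfoldable=tuple(j < n_unfoldable for j in range(n_total)),
        )

    @property
    def n_total(self) -> int:
        return len(self.params)

    @property
    def n_unfoldable(self) -> int:
        return int(sum(self.unfoldable))

    def arrays(self):
        """(k0, dx, unfoldable) as numpy arrays over the rod subdomains."""
        k0 = np.array([p.k0 for p in self.params], dtype=float)
        dx = np.array([p.dx for p in self.params], dtype=float)
        unf = np.array(self.unfoldable, dtype=bool)
        return k0, dx, unf


@dataclass(frozen=True)
class CatchSlipParams:
    """Two-bound-state catch--slip bond (0 unbound, 1 fast, 2 slow).

    Defaults are the strongest of the three catch-bond parameter sets
    studied for the Talin-integrin linkage; only the ratio k12_0/k21_0
    (0.142) is constrained at rapid equilibrium, so k21_0 is fixed at
    1 1/s by convention.
    """

    k10_0: float = 0.194
    k12_0: float = 0.142
    k21_0: float = 1.0
    k20_0: float = 5.5e-6
    x10: float = 0.0
    x20: float = 2.5
    x12: float = 0.4
    x21: float = -1.6

    def __post_init__(self) -> None:
        for name in ("k10_0", "k12_0", "k21_0", "k20_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def bell_rate(F, params: BellParams, kT: float):
    """Bell's law k(F) = k0 exp(F dx / kT), 1/s.

    The exponent is capped at 700 to avoid overflow; capped rates are
    astronomically large and certain on any finite timestep.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")
    expo = np.minimum(F * params.dx / kT, _EXP_CAP)
    out = params.k0 * np.exp(expo)
    return float(out) if out.ndim == 0 else out


def catch_slip_unbind_rate(F, params: CatchSlipParams, kT: float):
    """Overall dissociation rate of the catch--slip bond at force F, 1/s.

    (k21(F) k10(F) + k12(F) k20(F)) / (k12(F) + k21(F)) with each
    k_ij(F) = k_ij0 exp(F x_ij / kT).  At F = 0 with the default
    parameters this evaluates to 0.194/1.142 ~ 0.17 1/s, the measured
    zero-force rate.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be >= 0")

    def k(k0: float, x: float):
        return k0 * np.exp(np.minimum(F * x / kT, _EXP_CAP))

    k10 = k(params.k10_0, params.x10)
    k20 = k(params.k20_0, params.x20)
    k12 = k(params.k12_0, params.x12)
    k21 = k(params.k21_0, params.x21)
    out = (k21 * k10 + k12 * k20) / (k12 + k21)
    return float(out) if out.ndim == 0 else out


def unbind_rate(F, unbind, kT: float):
    """Dispatch on the bond model: BellParams (slip) or CatchSlipParams."""
    if isinstance(unbind, BellParams):
        return bell_rate(F, unbind, kT)
    if isinstance(unbind, CatchSlipParams):
        return catch_slip_unbind_rate(F, unbind, kT)
    raise TypeError(f"unsupported unbinding model: {type(unbind).__name__}")
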