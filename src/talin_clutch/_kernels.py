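"""Numba-compiled numerical cores.

Scalar FJC/Langevin helpers, the uniform-tension Newton solve, the
discrete-time master-equation sweeps (homogeneous over the number of
unfolded subdomains, heterogeneous over subdomain bit-states) and the
overdamped bead--spring pulling trace.  The Python modules wrap these
with validated dataclasses; everything here works on plain floats and
arrays so it can be jitted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_CAP = 700.0


@njit(cache=True)
def _langevin(y):
    if abs(y) < 1e-4:
        return y / 3.0 - y * y * y / 45.0
    return 1.0 / np.tanh(y) - 1.0 / y


@njit(cache=True)
def _dlangevin(y):
    if abs(y) < 1e-4:
        return 1.0 / 3.0 - y * y / 15.0
    if y > 350.0:
        return 1.0 / (y * y)
    s = np.sinh(y)
    return 1.0 / (y * y) - 1.0 / (s * s)


@njit(cache=True)
def _inv_langevin(x):
    """Pade seed + Newton polish; x in [0, 1)."""
    if x < 1e-10:
        return 3.0 * x
    if x > 0.999999:
        x = 0.999999
    y = x * (3.0 - x * x) / (1.0 - x * x)
    for _ in range(4):
        f = _langevin(y) - x
        fp = _dlangevin(y)
        if fp <= 0.0:
            break
        step = f / fp
        yn = y - step
        if yn <= 0.0:
            yn = 0.5 * y
        y = yn
        if abs(step) <= 1e-12 * y:
            break
    return y


@njit(cache=True)
def _solve_tension_scalar(L_tot, i, n_seg, l0, k_nm, b, nres, kT, tau_init):
    """Monotone root solve for the uniform tension; Newton with a
    bisection fallback, warm-started at ``tau_init``."""
    Lc = b * nres
    rest = (n_seg - i) * l0
    if i == 0:
        l = L_tot / n_seg
        d = l - l0
        if d <= 0.0:
            return 0.0
        return k_nm * d
    if L_tot <= rest:
        return 0.0

    tau = tau_init if tau_init > 1e-12 else 1.0
    converged = False
    for _ in range(60):
        lu = Lc * _langevin(tau * b / kT)
        lf = l0 + tau / k_nm
        f = i * lu + (n_seg - i) * lf - L_tot
        fp = i * (b * b * nres / kT) * _dlangevin(tau * b / kT) + (n_seg - i) / k_nm
        step = f / fp
        tn = tau - step
        if tn <= 0.0:
            tn = 0.5 * tau
        tau = tn
        if abs(step) <= 1e-12 * max(tau, 1.0):
            converged = True
            break
    if converged and tau > 0.0:
        lu = Lc * _langevin(tau * b / kT)
        lf = l0 + tau / k_nm
        if abs(i * lu + (n_seg - i) * lf - L_tot) < 1e-8:
            return tau

    # bisection fallback
    lo = 0.0
    hi = 1.0
    for _ in range(200):
        lu = Lc * _langevin(hi * b / kT)
        lf = l0 + hi / k_nm
        if i * lu + (n_seg - i) * lf > L_tot:
            break
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        lu = Lc * _langevin(mid * b / kT)
        lf = l0 + mid / k_nm
        if i * lu + (n_seg - i) * lf > L_tot:
            hi = mid
        else:
            lo = mid
        if hi - lo <= 1e-13 * max(hi, 1.0):
            break
    return 0.5 * (lo + hi)


@njit(cache=True)
def _unbind_rate(F, kind, p, kT):
    """kind 0: slip Bell (p[0]=k0, p[1]=dx); kind 1: catch-slip
    (p = k10_0, k12_0, k21_0, k20_0, x10, x20, x12, x21)."""
    if kind == 0:
        e = F * p[1] / kT
        if e > _EXP_CAP:
            e = _EXP_CAP
        return p[0] * np.exp(e)
    e10 = min(F * p[4] / kT, _EXP_CAP)
    e20 = min(F * p[5] / kT, _EXP_CAP)
    e12 = min(F * p[6] / kT, _EXP_CAP)
    e21 = min(F * p[7] / kT, _EXP_CAP)
    k10 = p[0] * np.exp(e10)
    k12 = p[1] * np.exp(e12)
    k21 = p[2] * np.exp(e21)
    k20 = p[3] * np.exp(e20)
    return (k21 * k10 + k12 * k20) / (k12 + k21)


@njit(cache=True)
def _bell(F, k0, dx, kT):
    e = F * dx / kT
    if e > _EXP_CAP:
        e = _EXP_CAP
    return k0 * np.exp(e)


@njit(cache=True)
def run_me_homogeneous(
    M, n_seg, L0, costheta, v, l0, k_nm, b, nres, kT,
    ku0, kdx, ub_kind, ub_params,
    dt, n_steps, step0, P_in, tau_in,
    P_out, F_out, U_out,
):
    """Advance the homogeneous master equation ``n_steps`` steps.

    State at entry is ``P_in`` (length M+1) at discrete time ``step0``;
    per-step records are written into ``P_out``/``F_out`` (state and
    tension at the start of each step) and ``U_out`` (unbinding mass
    removed during the step, per state).  Returns (steps_done, P, tau)
    where P/tau are the state after the last step (tau for warm starts).
    """
    P = P_in.copy()
    tau = tau_in.copy()
    newP = np.empty(M + 1)
    p_unf = np.empty(M + 1)
    p_unb = np.empty(M + 1)

    # binomial table C[m, k] for m <= M
    C = np.zeros((M + 1, M + 1))
    for m in range(M + 1):
        C[m, 0] = 1.0
        for k in range(1, m + 1):
            C[m, k] = C[m - 1, k - 1] + (C[m - 1, k] if k <= m - 1 else 0.0)

    done = 0
    for n in range(n_steps):
        t = (step0 + n) * dt
        L = np.sqrt(L0 * L0 + 2.0 * L0 * v * t * costheta + v * v * t * t)
        for i in range(M + 1):
            tau[i] = _solve_tension_scalar(L, i, n_seg, l0, k_nm, b, nres, kT, tau[i])
            p_unf[i] = -np.expm1(-_bell(tau[i], ku0, kdx, kT) * dt)
            p_unb[i] = -np.expm1(-_unbind_rate(tau[i], ub_kind, ub_params, kT) * dt)
            P_out[n, i] = P[i]
            F_out[n, i] = tau[i]
            U_out[n, i] = p_unb[i] * P[i]

        for j in range(M + 1):
            acc = 0.0
            for i in range(j + 1):
                p = p_unf[i]
                # A_ij = C(M-i, j-i) (1-p)^(M-j) p^(j-i)
                acc += P[i] * C[M - i, j - i] * (1.0 - p) ** (M - j) * p ** (j - i)
            newP[j] = acc - p_unb[j] * P[j]
        for j in range(M + 1):
            P[j] = newP[j]
        done = n + 1
    return done, P, tau


@njit(cache=True)
def run_me_heterogeneous(
    M, n_seg, L0, costheta, v, l0, k_nm, b, nres, kT,
    ku0, kdx, ub_kind, ub_params,
    dt, n_steps, step0, P_in, tau_in,
    Pc_out, F_out, Uc_out,
):
    """Heterogeneous master equation over 2^M subdomain bit-states.

    ``ku0``/``kdx`` are per-subdomain arrays (length M, unfoldable rod
    subdomains only; permanently folded subdomains contribute segments
    but no states).  Tension depends on the state only through the
    number of unfolded subdomains, so per-count records aggregated over
    states with equal popcount are written out (same layout as the
    homogeneous kernel) for direct comparison.
    """
    n_states = 1 << M
    full = n_states - 1
    pop = np.zeros(n_states, dtype=np.int64)
    for s in range(1, n_states):
        pop[s] = pop[s >> 1] + (s & 1)

    P = P_in.copy()
    tau = tau_in.copy()
    newP = np.empty(n_states)
    p_unb = np.empty(M + 1)
    p_unf = np.empty((M + 1, M))

    done = 0
    for n in range(n_steps):
        t = (step0 + n) * dt
        L = np.sqrt(L0 * L0 + 2.0 * L0 * v * t * costheta + v * v * t * t)
        for c in range(M + 1):
            tau[c] = _solve_tension_scalar(L, c, n_seg, l0, k_nm, b, nres, kT, tau[c])
            p_unb[c] = -np.expm1(-_unbind_rate(tau[c], ub_kind, ub_params, kT) * dt)
            for j in range(M):
                p_unf[c, j] = -np.expm1(-_bell(tau[c], ku0[j], kdx[j], kT) * dt)
            F_out[n, c] = tau[c]
            Pc_out[n, c] = 0.0
            Uc_out[n, c] = 0.0

        for s in range(n_states):
            c = pop[s]
            Pc_out[n, c] += P[s]
            Uc_out[n, c] += p_unb[c] * P[s]

        for s in range(n_states):
            newP[s] = -p_unb[pop[s]] * P[s]
        for s in range(n_states):
            Ps = P[s]
            if Ps <= 0.0:
                continue
            c = pop[s]
            fm = full & ~s  # still-folded subdomains
            sub = fm
            while True:
                w = Ps
                for j in range(M):
                    bit = 1 << j
                    if fm & bit:
                        if sub & bit:
                            w *= p_unf[c, j]
                        else:
                            w *= 1.0 - p_unf[c, j]
                newP[s | sub] += w
                if sub == 0:
                    break
                sub = (sub - 1) & fm
        for s in range(n_states):
            P[s] = newP[s]
        done = n + 1
    return done, P, tau


@njit(cache=True)
def run_pulling(
    pos0, fixed_idx, driven_idx,
    seg_k, seg_rest, seg_is_rod, seg_unfolded0,
    seg_ku0, seg_kdx, seg_unfoldable,
    unbind_seg, ub_kind, ub_params,
    l0, k_nm, b, nres, kT,
    zeta, dt, v, t_max, seed,
):
    """One stochastic pulling trace.

    Forward-Euler overdamped bead update; the fixed bead has zero
    velocity, the driven bead advances at ``v`` in +x.  Unfolding and
    unbinding fire when the accumulated hazard of a channel (local
    segment tension through Bell's law / the catch-slip rate) crosses a
    pre-drawn unit-exponential threshold, which is exact for
    time-varying rates.

    Returns (status, t_end, work, n_unfolds, ev_time, ev_seg, ev_tension,
    pos) where status is 0 = unbound, 1 = censored at t_max,
    2 = numerical instability (bead moved > 1 nm in one step).
    """
    np.random.seed(seed)
    n_beads = pos0.shape[0]
    n_segs = n_beads - 1
    pos = pos0.copy()
    frc = np.zeros((n_beads, 2))
    seg_unfolded = seg_unfolded0.copy()
    tau = np.zeros(n_segs)

    haz = np.zeros(n_segs + 1)        # [0] unbind, [1+s] per-segment unfold
    thr = np.empty(n_segs + 1)
    for c in range(n_segs + 1):
        thr[c] = np.random.exponential()

    max_events = n_segs + 1
    ev_time = np.zeros(max_events)
    ev_seg = np.zeros(max_events, dtype=np.int64)
    ev_tension = np.zeros(max_events)
    n_ev = 0

    Lc = b * nres
    work = 0.0
    t = 0.0
    n_steps = int(round(t_max / dt))
    status = 1
    inv_zeta_dt = dt / zeta
    max_disp = 0.0

    for n in range(n_steps):
        for i in range(n_beads):
            frc[i, 0] = 0.0
            frc[i, 1] = 0.0
        for s in range(n_segs):
            dx = pos[s + 1, 0] - pos[s, 0]
            dy = pos[s + 1, 1] - pos[s, 1]
            r = np.sqrt(dx * dx + dy * dy)
            if r < 1e-12:
                tau[s] = 0.0
                continue
            if seg_unfolded[s]:
                x = r / Lc
                if x >= 1.0:
                    x = 0.999999
                f = (kT / b) * _inv_langevin(x)
            else:
                d = r - seg_rest[s]
                f = seg_k[s] * d if d > 0.0 else 0.0
            tau[s] = f
            ux = dx / r
            uy = dy / r
            frc[s, 0] += f * ux
            frc[s, 1] += f * uy
            frc[s + 1, 0] -= f * ux
            frc[s + 1, 1] -= f * uy

        for i in range(n_beads):
            if i == fixed_idx or i == driven_idx:
                continue
            mx = frc[i, 0] * inv_zeta_dt
            my = frc[i, 1] * inv_zeta_dt
            d2 = mx * mx + my * my
            if d2 > max_disp:
                max_disp = d2
            if d2 > 1.0:
                status = 2
                return status, t, work, n_ev, ev_time[:n_ev], ev_seg[:n_ev], ev_tension[:n_ev], pos
            pos[i, 0] += mx
            pos[i, 1] += my
        pos[driven_idx, 0] += v * dt

        # work done on the driven (actin-side) anchor along the flow axis
        dxs = pos[driven_idx, 0] - pos[driven_idx - 1, 0]
        dys = pos[driven_idx, 1] - pos[driven_idx - 1, 1]
        rs = np.sqrt(dxs * dxs + dys * dys)
        if rs > 1e-12:
            work += tau[driven_idx - 1] * (dxs / rs) * v * dt

        t = (n + 1) * dt

        haz[0] += _unbind_rate(tau[unbind_seg], ub_kind, ub_params, kT) * dt
        if haz[0] >= thr[0]:
            status = 0
            return status, t, work, n_ev, ev_time[:n_ev], ev_seg[:n_ev], ev_tension[:n_ev], pos
        for s in range(n_segs):
            if seg_is_rod[s] and seg_unfoldable[s] and not seg_unfolded[s]:
                haz[1 + s] += _bell(tau[s], seg_ku0[s], seg_kdx[s], kT) * dt
                if haz[1 + s] >= thr[1 + s]:
                    seg_unfolded[s] = True
                    ev_time[n_ev] = t
                    ev_seg[n_ev] = s
                    ev_tension[n_ev] = tau[s]
                    n_ev += 1

    return status, t, work, n_ev, ev_time[:n_ev], ev_seg[:n_ev], ev_tension[:n_ev], pos
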