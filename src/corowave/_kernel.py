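"""JIT-compiled inner loop of the network time integration.

The per-step work (Richtmyer interior update, characteristic boundary
closures, impedance convolution) is written in plain loop form so that
numba can compile it; without numba the same functions run as ordinary
(slow) Python, and the solver falls back to its vectorized numpy cycle
implementation instead.  Semantics must mirror
:mod:`corowave.solver`'s reference closures exactly; a regression test
asserts the two paths agree.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap

# status codes returned by the kernel
OK = 0
NEGATIVE_AREA = 1
CFL_VIOLATION = 2
NEWTON_FAIL_JUNCTION = 3
NEWTON_FAIL_OUTLET = 4
NEWTON_FAIL_INLET = 5


@njit(cache=True)
def _c_of(A, A0, f, rho, linear):
    if linear:
        return math.sqrt(f * A0 / (rho * A))
    return math.sqrt(0.5 * f / rho) * (A0 / A) ** 0.25


@njit(cache=True)
def _area_of_p(p, A0, f, p0, linear):
    y = (p - p0) / f
    if y > 0.999:
        y = 0.999
    if linear:
        return A0 / (1.0 - y)
    return A0 / ((1.0 - y) * (1.0 - y))


@njit(cache=True)
def _char_W(A, Q, b, i, dt, dxb, A0, f, rho, linear, kappa, forward):
    """Outgoing Riemann invariant at boundary node b, interpolated at the foot."""
    Ab = A[b]
    Ai = A[i]
    ub = Q[b] / Ab
    ui = Q[i] / Ai
    cb = _c_of(Ab, A0[b], f[b], rho, linear)
    ci = _c_of(Ai, A0[i], f[i], rho, linear)
    if forward:
        lam = ub + cb
    else:
        lam = cb - ub
    xi = lam * dt / dxb
    if xi < 0.0:
        xi = 0.0
    elif xi > 1.0:
        xi = 1.0
    c0b = _c_of(A0[b], A0[b], f[b], rho, linear)
    c0i = _c_of(A0[i], A0[i], f[i], rho, linear)
    sgn = 1.0 if forward else -1.0
    Wb = ub + sgn * kappa * (c0b - cb)
    Wi = ui + sgn * kappa * (c0i - ci)
    return (1.0 - xi) * Wb + xi * Wi


@njit(cache=True)
def _u_of_A(Ai, A0b, fb, W, rho, linear, kappa, forward):
    c0 = _c_of(A0b, A0b, fb, rho, linear)
    c = _c_of(Ai, A0b, fb, rho, linear)
    sgn = 1.0 if forward else -1.0
    return W - sgn * kappa * (c0 - c)


@njit(cache=True)
def run_cycle(
    A, Q, An, Qn, qhist,
    steps, m_sub, dt, dtau,
    # node geometry
    A0, f, fp, dr0dx, r0, dxn, p0,
    # interfaces
    ifL, ifR, A0h, fh, fph, dr0dxh, r0h, dxh,
    int_nodes, int_ifL, int_ifR,
    rho, mu, delta, linear, kappa,
    # junctions (nj, 6): p_b, p_i, d1_b, d1_i, d2_b, d2_i
    jn_nodes,
    # outlets
    term_b, z0_dt, ker_rest, pf_fine, conv_off,
    # inlets
    root_b, flow_mode, p_in_fine, q_in_fine, scale,
    junction_tol, max_newton,
    A_coarse, Q_coarse,
    # per-vessel first/last interface indices and flux integrals
    vif_first, vif_last, vol_in, vol_out,
    # scratch
    F1, F2, S, Ah, Qh, F1h, F2h, Sh,
):
    """One cardiac cycle of ``steps`` substeps; returns (status, node, worst_res)."""
    n_nodes = A.shape[0]
    n_if = ifL.shape[0]
    nj = jn_nodes.shape[0]
    nt = term_b.shape[0]
    nr = root_b.shape[0]
    nk = conv_off.shape[0]
    sqpi = math.sqrt(math.pi)
    worst = 0.0
    nu = mu / rho

    for n in range(steps):
        n1 = (n + 1) % steps
        # --- node fluxes and sources --------------------------------
        for k in range(n_nodes):
            a = A[k]
            if a <= 0.0:
                return NEGATIVE_AREA, k, worst
            q = Q[k]
            u = q / a
            sqa = math.sqrt(a)
            F1[k] = q
            if linear:
                F2[k] = q * u + (f[k] * A0[k] / rho) * math.log(a / A0[k])
                s_tap = 0.0
            else:
                F2[k] = q * u + (f[k] / rho) * math.sqrt(A0[k]) * sqa
                s_tap = (dr0dx[k] / rho) * (
                    2.0 * sqpi * sqa * (f[k] + r0[k] * fp[k]) - a * fp[k]
                )
            r_inst = sqa / sqpi
            S[k] = s_tap - 2.0 * math.pi * nu * r_inst * q / (delta * a)
            # CFL monitor
            c = _c_of(a, A0[k], f[k], rho, linear)
            if (abs(u) + c) * dt > dxn[k]:
                return CFL_VIOLATION, k, worst
        # --- half steps ---------------------------------------------
        for k in range(n_if):
            l = ifL[k]
            r = ifR[k]
            lam = dt / dxh[k]
            a = 0.5 * (A[l] + A[r]) - 0.5 * lam * (F1[r] - F1[l])
            q = 0.5 * (Q[l] + Q[r]) - 0.5 * lam * (F2[r] - F2[l]) + 0.25 * dt * (S[l] + S[r])
            if a <= 0.0:
                return NEGATIVE_AREA, l, worst
            Ah[k] = a
            Qh[k] = q
            u = q / a
            sqa = math.sqrt(a)
            F1h[k] = q
            if linear:
                F2h[k] = q * u + (fh[k] * A0h[k] / rho) * math.log(a / A0h[k])
                s_tap = 0.0
            else:
                F2h[k] = q * u + (fh[k] / rho) * math.sqrt(A0h[k]) * sqa
                s_tap = (dr0dxh[k] / rho) * (
                    2.0 * sqpi * sqa * (fh[k] + r0h[k] * fph[k]) - a * fph[k]
                )
            r_inst = sqa / sqpi
            Sh[k] = s_tap - 2.0 * math.pi * nu * r_inst * q / (delta * a)
        # boundary-interface flux integrals (per-vessel volume budget)
        for v in range(vif_first.shape[0]):
            vol_in[v] += F1h[vif_first[v]] * dt
            vol_out[v] += F1h[vif_last[v]] * dt
        # --- interior update ----------------------------------------
        for kk in range(n_nodes):
            An[kk] = A[kk]
            Qn[kk] = Q[kk]
        for idx in range(int_nodes.shape[0]):
            k = int_nodes[idx]
            il = int_ifL[idx]
            ir = int_ifR[idx]
            lam = dt / dxn[k]
            a = A[k] - lam * (F1h[ir] - F1h[il])
            if a <= 0.0:
                return NEGATIVE_AREA, k, worst
            An[k] = a
            Qn[k] = Q[k] - lam * (F2h[ir] - F2h[il]) + 0.5 * dt * (Sh[il] + Sh[ir])
        # --- inlets --------------------------------------------------
        for ri in range(nr):
            b = root_b[ri]
            i = b + 1
            W = _char_W(A, Q, b, i, dt, dxn[b], A0, f, rho, linear, kappa, False)
            if flow_mode:
                q_t = q_in_fine[ri, n1]
                Ai = A[b]
                ok = False
                for it in range(max_newton):
                    u = _u_of_A(Ai, A0[b], f[b], W, rho, linear, kappa, False)
                    c = _c_of(Ai, A0[b], f[b], rho, linear)
                    G = Ai * u - q_t
                    if abs(G) < 1e-12 * max(abs(q_t), 1.0):
                        ok = True
                        break
                    Ai -= G / (u + c)
                    if Ai < 0.2 * A0[b]:
                        Ai = 0.2 * A0[b]
                if not ok:
                    return NEWTON_FAIL_INLET, b, worst
            else:
                Ai = _area_of_p(scale * p_in_fine[n1], A0[b], f[b], p0[b], linear)
            u = _u_of_A(Ai, A0[b], f[b], W, rho, linear, kappa, False)
            An[b] = Ai
            Qn[b] = Ai * u
        # --- junctions ----------------------------------------------
        for j in range(nj):
            pb = jn_nodes[j, 0]
            pi = jn_nodes[j, 1]
            d1b = jn_nodes[j, 2]
            d1i = jn_nodes[j, 3]
            d2b = jn_nodes[j, 4]
            d2i = jn_nodes[j, 5]
            Wp = _char_W(A, Q, pb, pi, dt, dxn[pb], A0, f, rho, linear, kappa, True)
            W1 = _char_W(A, Q, d1b, d1i, dt, dxn[d1b], A0, f, rho, linear, kappa, False)
            W2 = _char_W(A, Q, d2b, d2i, dt, dxn[d2b], A0, f, rho, linear, kappa, False)
            # initial guess: parent boundary pressure at t_n
            if linear:
                p = p0[pb] + f[pb] * (1.0 - A0[pb] / A[pb])
            else:
                p = p0[pb] + f[pb] * (1.0 - math.sqrt(A0[pb] / A[pb]))
            q_scale = abs(Q[pb])
            alt = abs(Q[d1b]) + abs(Q[d2b])
            if alt > q_scale:
                q_scale = alt
            if q_scale < 1.0:
                q_scale = 1.0
            # damped Newton on the common pressure
            Fres = 0.0
            dF = 0.0
            Ap = A1 = A2 = 0.0
            qp = q1 = q2 = 0.0
            for attempt in range(max_newton + 1):
                Fres = 0.0
                dF = 0.0
                for vv in range(3):
                    if vv == 0:
                        bnode, W, fw = pb, Wp, True
                    elif vv == 1:
                        bnode, W, fw = d1b, W1, False
                    else:
                        bnode, W, fw = d2b, W2, False
                    Av = _area_of_p(p, A0[bnode], f[bnode], p0[bnode], linear)
                    uv = _u_of_A(Av, A0[bnode], f[bnode], W, rho, linear, kappa, fw)
                    cv = _c_of(Av, A0[bnode], f[bnode], rho, linear)
                    if linear:
                        dpda = f[bnode] * A0[bnode] / (Av * Av)
                    else:
                        dpda = 0.5 * f[bnode] * math.sqrt(A0[bnode]) / Av**1.5
                    dadp = 1.0 / dpda
                    sgn = 1.0 if fw else -1.0
                    Fres += sgn * Av * uv
                    dF += sgn * (uv - sgn * cv) * dadp
                    if vv == 0:
                        Ap, qp = Av, Av * uv
                    elif vv == 1:
                        A1, q1 = Av, Av * uv
                    else:
                        A2, q2 = Av, Av * uv
                if abs(Fres) <= junction_tol * q_scale:
                    break
                if attempt == max_newton:
                    return NEWTON_FAIL_JUNCTION, pb, worst
                step = -Fres / dF
                # damping: halve until residual decreases
                lam_d = 1.0
                F_old = abs(Fres)
                while lam_d > 1e-6:
                    p_try = p + lam_d * step
                    F_try = 0.0
                    for vv in range(3):
                        if vv == 0:
                            bnode, W, fw = pb, Wp, True
                        elif vv == 1:
                            bnode, W, fw = d1b, W1, False
                        else:
                            bnode, W, fw = d2b, W2, False
                        Av = _area_of_p(p_try, A0[bnode], f[bnode], p0[bnode], linear)
                        uv = _u_of_A(Av, A0[bnode], f[bnode], W, rho, linear, kappa, fw)
                        sgn = 1.0 if fw else -1.0
                        F_try += sgn * Av * uv
                    if abs(F_try) < F_old:
                        break
                    lam_d *= 0.5
                p = p + lam_d * step
            res = abs(Fres) / q_scale
            if res > worst:
                worst = res
            An[pb], Qn[pb] = Ap, qp
            An[d1b], Qn[d1b] = A1, q1
            An[d2b], Qn[d2b] = A2, q2
        # --- outlets -------------------------------------------------
        for tt in range(nt):
            b = term_b[tt]
            i = b - 1
            # history convolution excluding the current sample
            s = 0.0
            for jj in range(nk):
                idx2 = n - conv_off[jj]
                idx2 = idx2 % steps
                s += ker_rest[tt, jj] * qhist[tt, idx2]
            conv = dtau * s
            W = _char_W(A, Q, b, i, dt, dxn[b], A0, f, rho, linear, kappa, True)
            Ai = A[b]
            ok = False
            G = 0.0
            for it in range(max_newton):
                u = _u_of_A(Ai, A0[b], f[b], W, rho, linear, kappa, True)
                c = _c_of(Ai, A0[b], f[b], rho, linear)
                if linear:
                    pb_ = p0[b] + f[b] * (1.0 - A0[b] / Ai)
                    dpda = f[b] * A0[b] / (Ai * Ai)
                else:
                    pb_ = p0[b] + f[b] * (1.0 - math.sqrt(A0[b] / Ai))
                    dpda = 0.5 * f[b] * math.sqrt(A0[b]) / Ai**1.5
                G = pb_ - z0_dt[tt] * Ai * u - conv - pf_fine[tt, n1]
                if abs(G) < 1e-12 * max(abs(pb_), 1.0):
                    ok = True
                    break
                dG = dpda - z0_dt[tt] * (u - c)
                stp = -G / dG
                if Ai + stp <= 0.2 * A0[b]:
                    stp = 0.5 * (0.2 * A0[b] - Ai)
                Ai += stp
            if not ok:
                return NEWTON_FAIL_OUTLET, b, worst
            u = _u_of_A(Ai, A0[b], f[b], W, rho, linear, kappa, True)
            An[b] = Ai
            Qn[b] = Ai * u
        # --- commit ---------------------------------------------------
        for kk in range(n_nodes):
            A[kk] = An[kk]
            Q[kk] = Qn[kk]
        for tt in range(nt):
            qhist[tt, n] = Q[term_b[tt]]
        if n % m_sub == 0:
            kc = n // m_sub
            for kk in range(n_nodes):
                A_coarse[kk, kc] = A[kk]
                Q_coarse[kk, kc] = Q[kk]
    return OK, -1, worst
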