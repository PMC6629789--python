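"""1D pulse-wave solver on the coronary network.

Integrates the cross-sectionally averaged continuity and momentum
equations

    A_t + q_x = 0,
    q_t + (q^2/A)_x + (A/rho) p_x = -2 pi nu r q / (delta A),

closed by the tube law p - p0 = (4 Eh / 3 r0)(1 - sqrt(A0/A)), on every
vessel of the network, using the two-step (Richtmyer) Lax-Wendroff
scheme in conservation form with taper/stiffness-gradient source terms.
Boundaries are closed with the outgoing characteristic of each vessel:

* inlets: prescribed aortic-root pressure (or prescribed inflow),
* bifurcations: common static pressure + flow conservation, solved by a
  damped Newton iteration on the junction pressure,
* terminal outlets: periodic convolution of the vascular-bed impedance
  kernel with the outflow history, plus the myocardial feedback
  pressure p_f(t).

Internally everything is CGS; pressures enter and leave in mmHg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .config import MMHG, Config
from .geometry import CoronaryTree, load_vessel_table, split_trifurcation
from .heart import HeartDrive, VolumeModel, feedback_pressure, inlet_waveform
from .impedance import ImpedanceSpectrum, poiseuille_resistance, root_impedance

log = logging.getLogger("corowave")

__all__ = [
    "tube_law_pressure",
    "wave_speed",
    "VesselGrid",
    "Network",
    "lax_wendroff_step",
    "junction_solve",
    "outlet_update",
    "run_to_periodic",
    "RunResult",
    "build_default_network",
]


# ----------------------------------------------------------------------
# tube law
# ----------------------------------------------------------------------

def _stiffness(wall, r0):
    """f(r0) = (4/3) Eh/r0 and its derivative df/dr0 (CGS)."""
    f = (4.0 / 3.0) * (wall.k1 * np.exp(wall.k2 * r0) + wall.k3)
    fp = (4.0 / 3.0) * wall.k1 * wall.k2 * np.exp(wall.k2 * r0)
    return f, fp


def tube_law_pressure(A, A0, r0, wall):
    """Transmural pressure (mmHg) and dp/dA (CGS) of the tube law.

    Adopted form: p = p0 + f(r0) (1 - sqrt(A0/A)), f = (4/3) Eh/r0,
    which is the state equation behind the tabulated k1..k3; the
    monotone literal-linear variant p = p0 + f (1 - A0/A) is available
    via ``wall.linear_tube_law`` for sensitivity studies.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("non-positive cross-sectional area")
    f, _ = _stiffness(wall, r0)
    p0 = wall.p0_ref * MMHG
    if wall.linear_tube_law:
        p = p0 + f * (1.0 - A0 / A)
        dpda = f * A0 / A**2
    else:
        p = p0 + f * (1.0 - np.sqrt(A0 / A))
        dpda = 0.5 * f * np.sqrt(A0) / A**1.5
    return p / MMHG, dpda


def wave_speed(A, A0, f, rho, linear=False):
    """Local characteristic speed c = sqrt(A/rho dp/dA)."""
    if linear:
        return np.sqrt(f * A0 / (rho * A))
    return np.sqrt(0.5 * f / rho) * (A0 / A) ** 0.25


# ----------------------------------------------------------------------
# grids and network assembly
# ----------------------------------------------------------------------

@dataclass
class VesselGrid:
    """Uniform grid on one tapered vessel (node slice of the flat state)."""

    name: str
    start: int              # first node index in the flat arrays
    n: int                  # number of nodes
    dx: float
    length: float

    @property
    def stop(self) -> int:
        return self.start + self.n

    @property
    def mid(self) -> int:
        """Flat index of the midpoint node."""
        return self.start + (self.n - 1) // 2


@dataclass
class _Junction:
    parent: str
    d1: str
    d2: str
    # flat node indices: parent distal, its interior neighbour; daughters
    # proximal, their interior neighbours
    p_b: int
    p_i: int
    d1_b: int
    d1_i: int
    d2_b: int
    d2_i: int


class Network:
    """Discretized coronary network with flat state arrays.

    Nodes of all vessels are concatenated into flat arrays; interfaces
    (j+1/2 points of the Richtmyer scheme) likewise.  Per-node geometry
    (r0, A0, stiffness, reference pressure) is precomputed.
    """

    def __init__(self, tree: CoronaryTree, cfg: Config):
        if any(len(s.daughters) not in (0, 2) for s in tree.segments.values()):
            raise ValueError("network requires a binary tree (split the trifurcation first)")
        self.tree = tree
        self.cfg = cfg
        self.rho = cfg.fluid.rho
        self.mu = cfg.fluid.mu
        self.linear = cfg.wall.linear_tube_law
        # boundary-layer thickness of the oscillatory viscous layer
        self.delta = math.sqrt(cfg.fluid.nu * cfg.ventricle_left.t_c / (2.0 * math.pi))
        self.kappa = 2.0 if self.linear else 4.0  # Riemann-invariant factor

        num = cfg.numerics
        self.grids: Dict[str, VesselGrid] = {}
        xs, r0s, dxs, names = [], [], [], []
        start = 0
        order = list(tree.segments)
        for name in order:
            seg = tree[name]
            ncell = max(num.min_nodes - 1, int(math.ceil(seg.length / num.dx_max)))
            n = ncell + 1
            dx = seg.length / ncell
            g = VesselGrid(name=name, start=start, n=n, dx=dx, length=seg.length)
            self.grids[name] = g
            x = np.linspace(0.0, seg.length, n)
            xs.append(x)
            r0s.append(seg.r_prox + (seg.r_dist - seg.r_prox) * x / seg.length)
            dxs.append(np.full(n, dx))
            start += n
        self.n_nodes = start
        self.x = np.concatenate(xs)
        self.r0 = np.concatenate(r0s)
        self.dxn = np.concatenate(dxs)
        self.A0 = np.pi * self.r0**2
        self.f, self.fp = _stiffness(cfg.wall, self.r0)
        self.dr0dx = np.concatenate(
            [
                np.full(self.grids[nm].n, (tree[nm].r_dist - tree[nm].r_prox) / tree[nm].length)
                for nm in order
            ]
        )
        # per-side reference pressure (CGS), filled by the driver
        self.p0 = np.zeros(self.n_nodes)
        self.side = np.array([tree.side(nm) for nm in order])
        self._order = order

        # interfaces: pairs (k, k+1) within each vessel
        L, iface_of = [], {}
        for nm in order:
            g = self.grids[nm]
            iface_of[nm] = len(L)
            L.extend(range(g.start, g.stop - 1))
        self.ifL = np.array(L, dtype=np.intp)
        self.ifR = self.ifL + 1
        self.n_if = len(L)
        # half-point geometry
        self.r0h = 0.5 * (self.r0[self.ifL] + self.r0[self.ifR])
        self.A0h = np.pi * self.r0h**2
        self.fh, self.fph = _stiffness(cfg.wall, self.r0h)
        self.dr0dxh = self.dr0dx[self.ifL]
        self.dxh = self.dxn[self.ifL]
        self.p0h = np.zeros(self.n_if)

        # interior nodes and their flanking interfaces
        INT, INT_L, INT_R = [], [], []
        for nm in order:
            g = self.grids[nm]
            i0 = iface_of[nm]
            for k in range(1, g.n - 1):
                INT.append(g.start + k)
                INT_L.append(i0 + k - 1)
                INT_R.append(i0 + k)
        self.int_nodes = np.array(INT, dtype=np.intp)
        self.int_ifL = np.array(INT_L, dtype=np.intp)
        self.int_ifR = np.array(INT_R, dtype=np.intp)
        # first/last interface of each vessel (volume-budget fluxes)
        self.vif_first = np.array([iface_of[nm] for nm in order], dtype=np.int64)
        self.vif_last = np.array(
            [iface_of[nm] + self.grids[nm].n - 2 for nm in order], dtype=np.int64
        )

        # junctions
        self.junctions: List[_Junction] = []
        for nm in order:
            seg = tree[nm]
            if len(seg.daughters) == 2:
                gp = self.grids[nm]
                g1 = self.grids[seg.daughters[0]]
                g2 = self.grids[seg.daughters[1]]
                self.junctions.append(
                    _Junction(
                        parent=nm,
                        d1=seg.daughters[0],
                        d2=seg.daughters[1],
                        p_b=gp.stop - 1,
                        p_i=gp.stop - 2,
                        d1_b=g1.start,
                        d1_i=g1.start + 1,
                        d2_b=g2.start,
                        d2_i=g2.start + 1,
                    )
                )
        self.terminals = [nm for nm in order if tree[nm].terminal]
        self.roots = list(tree.roots)

    # -- helpers on flat arrays -----------------------------------------
    def set_reference_pressure(self, p0_left_mmhg: float, p0_right_mmhg: float) -> None:
        vals = {"left": p0_left_mmhg * MMHG, "right": p0_right_mmhg * MMHG}
        for nm in self._order:
            g = self.grids[nm]
            self.p0[g.start : g.stop] = vals[self.tree.side(nm)]
            # interfaces inherit the vessel's side
        p0_if = np.empty(self.n_if)
        p0_if[:] = self.p0[self.ifL]
        self.p0h = p0_if

    def c0(self):
        return wave_speed(self.A0, self.A0, self.f, self.rho, self.linear)

    def pressure(self, A):
        """Transmural pressure at nodes, CGS (A may be (n_nodes,) or (n_nodes, k))."""
        A = np.asarray(A)
        p0 = self.p0 if A.ndim == 1 else self.p0[:, None]
        f = self.f if A.ndim == 1 else self.f[:, None]
        A0 = self.A0 if A.ndim == 1 else self.A0[:, None]
        if self.linear:
            return p0 + f * (1.0 - A0 / A)
        return p0 + f * (1.0 - np.sqrt(A0 / A))

    def area_of_pressure(self, p_cgs, idx):
        """Invert the tube law at node ``idx`` (scalar)."""
        f = self.f[idx]
        y = (p_cgs - self.p0[idx]) / f
        y = min(y, 0.999)
        if self.linear:
            return self.A0[idx] / (1.0 - y)
        return self.A0[idx] / (1.0 - y) ** 2


# ----------------------------------------------------------------------
# interior scheme
# ----------------------------------------------------------------------

def _flux_source(net: Network, A, Q, A0, f, fp, dr0dx, r0):
    """Conservative flux (F1, F2) and momentum source at given points."""
    rho = net.rho
    u = Q / A
    sqA = np.sqrt(A)
    F1 = Q
    if net.linear:
        F2 = Q * u + (f * A0 / rho) * np.log(A / A0)
        # taper source only supported for the adopted law
        S_tap = 0.0 * A
    else:
        sqA0 = np.sqrt(A0)
        F2 = Q * u + (f / rho) * sqA0 * sqA
        S_tap = (dr0dx / rho) * (
            2.0 * np.sqrt(np.pi) * sqA * (f + r0 * fp) - A * fp
        )
    r_inst = sqA / math.sqrt(math.pi)
    S_fric = -2.0 * math.pi * (net.mu / rho) * r_inst * Q / (net.delta * A)
    return F1, F2, S_tap + S_fric


def lax_wendroff_step(net: Network, A, Q, dt, return_flux: bool = False):
    """Advance interior nodes one step with the two-step Richtmyer scheme.

    Returns new (A, Q) arrays with boundary nodes left at their old
    values (boundary closures overwrite them afterwards); with
    ``return_flux`` also the half-step area flux at every interface
    (the fluxes through which the scheme conserves volume exactly).
    Raises if any area becomes non-positive.
    """
    F1, F2, S = _flux_source(net, A, Q, net.A0, net.f, net.fp, net.dr0dx, net.r0)
    L, R = net.ifL, net.ifR
    lam = dt / net.dxh
    Ah = 0.5 * (A[L] + A[R]) - 0.5 * lam * (F1[R] - F1[L])
    Qh = 0.5 * (Q[L] + Q[R]) - 0.5 * lam * (F2[R] - F2[L]) + 0.25 * dt * (S[L] + S[R])
    if np.any(Ah <= 0.0):
        k = int(np.argmin(Ah))
        raise FloatingPointError(f"negative area at interface {k} (x={net.x[net.ifL[k]]:.3f})")
    F1h, F2h, Sh = _flux_source(net, Ah, Qh, net.A0h, net.fh, net.fph, net.dr0dxh, net.r0h)
    An, Qn = A.copy(), Q.copy()
    I, IL, IR = net.int_nodes, net.int_ifL, net.int_ifR
    lam_i = dt / net.dxn[I]
    An[I] = A[I] - lam_i * (F1h[IR] - F1h[IL])
    Qn[I] = Q[I] - lam_i * (F2h[IR] - F2h[IL]) + 0.5 * dt * (Sh[IL] + Sh[IR])
    if np.any(An[I] <= 0.0):
        k = int(I[np.argmin(An[I])])
        raise FloatingPointError(f"negative area at node {k} (x={net.x[k]:.3f})")
    if return_flux:
        return An, Qn, F1h
    return An, Qn


# ----------------------------------------------------------------------
# characteristic extraction at boundaries
# ----------------------------------------------------------------------

def _char_out(net: Network, A, Q, b: int, i: int, dt: float, forward: bool):
    """Outgoing Riemann invariant at boundary node ``b`` at t+dt.

    ``i`` is the flanking interior node; ``forward`` selects the u+c
    family (distal boundaries) versus u-c (proximal boundaries).  The
    invariant W = u +/- kappa (c0 - c(A)) is interpolated at the foot of
    the characteristic traced back from the boundary over dt.
    """
    rho, lin, kap = net.rho, net.linear, net.kappa
    Ab, Ai = A[b], A[i]
    ub, ui = Q[b] / Ab, Q[i] / Ai
    cb = wave_speed(Ab, net.A0[b], net.f[b], rho, lin)
    lam = (ub + cb) if forward else (cb - ub)
    xi = min(max(lam * dt / net.dxn[b], 0.0), 1.0)
    # field values of W at boundary node and neighbour (local c0)
    c0b = wave_speed(net.A0[b], net.A0[b], net.f[b], rho, lin)
    c0i = wave_speed(net.A0[i], net.A0[i], net.f[i], rho, lin)
    ci = wave_speed(Ai, net.A0[i], net.f[i], rho, lin)
    sgn = 1.0 if forward else -1.0
    Wb = ub + sgn * kap * (c0b - cb)
    Wi = ui + sgn * kap * (c0i - ci)
    return (1.0 - xi) * Wb + xi * Wi


def _u_of_A(net: Network, idx: int, A: float, W: float, forward: bool) -> float:
    c0 = wave_speed(net.A0[idx], net.A0[idx], net.f[idx], net.rho, net.linear)
    c = wave_speed(A, net.A0[idx], net.f[idx], net.rho, net.linear)
    sgn = 1.0 if forward else -1.0
    return W - sgn * net.kappa * (c0 - c)


# ----------------------------------------------------------------------
# boundary closures
# ----------------------------------------------------------------------

def junction_solve(net: Network, A, Q, jn: _Junction, dt: float, tol: float, maxit: int):
    """Common-pressure bifurcation closure.

    Enforces q_p = q_d1 + q_d2 and p_p = p_d1 = p_d2 at the shared node,
    combined with the outgoing characteristic of each vessel, by damped
    Newton iteration on the junction pressure.  Returns the boundary
    (A, q) triples and the final flow residual.
    """
    Wp = _char_out(net, A, Q, jn.p_b, jn.p_i, dt, forward=True)
    W1 = _char_out(net, A, Q, jn.d1_b, jn.d1_i, dt, forward=False)
    W2 = _char_out(net, A, Q, jn.d2_b, jn.d2_i, dt, forward=False)
    nodes = (jn.p_b, jn.d1_b, jn.d2_b)
    Ws = (Wp, W1, W2)
    fwd = (True, False, False)
    p = float(net.pressure(A)[jn.p_b])  # initial guess: old parent pressure
    q_scale = max(abs(Q[jn.p_b]), abs(Q[jn.d1_b]) + abs(Q[jn.d2_b]), 1.0)

    def resid(p):
        F = 0.0
        dF = 0.0
        out = []
        for idx, W, fw in zip(nodes, Ws, fwd):
            Ai = net.area_of_pressure(p, idx)
            ui = _u_of_A(net, idx, Ai, W, fw)
            ci = wave_speed(Ai, net.A0[idx], net.f[idx], net.rho, net.linear)
            dpda = (
                net.f[idx] * net.A0[idx] / Ai**2
                if net.linear
                else 0.5 * net.f[idx] * math.sqrt(net.A0[idx]) / Ai**1.5
            )
            dAdp = 1.0 / dpda
            sgn = 1.0 if fw else -1.0
            dqdp = (ui - sgn * ci) * dAdp
            F += sgn * Ai * ui
            dF += sgn * dqdp
            out.append((Ai, Ai * ui))
        return F, dF, out

    F, dF, out = resid(p)
    it = 0
    while abs(F) > tol * q_scale and it < maxit:
        step = -F / dF
        lam = 1.0
        while lam > 1e-6:
            Fn, dFn, outn = resid(p + lam * step)
            if abs(Fn) < abs(F):
                break
            lam *= 0.5
        p += lam * step
        F, dF, out = Fn, dFn, outn
        it += 1
    if abs(F) > tol * q_scale:
        raise RuntimeError(
            f"junction {jn.parent} Newton failed: residual {F / q_scale:.3e}"
        )
    return out, abs(F) / q_scale


def outlet_update(net: Network, A, Q, b: int, i: int, dt: float,
                  z0_dt: float, conv_hist: float, p_f: float,
                  tol: float, maxit: int):
    """Terminal outlet closure: impedance convolution plus feedback.

    Solves p(A) = z(0) dtau * q + conv_hist + p_f together with the
    outgoing characteristic for the boundary (A, q).  ``conv_hist`` is
    the convolution over the stored outflow history excluding the
    current sample; all pressures CGS.
    """
    W = _char_out(net, A, Q, b, i, dt, forward=True)
    Ai = float(A[b])
    f, A0, p0 = net.f[b], net.A0[b], net.p0[b]
    for it in range(maxit):
        u = _u_of_A(net, b, Ai, W, True)
        c = wave_speed(Ai, A0, f, net.rho, net.linear)
        if net.linear:
            p = p0 + f * (1.0 - A0 / Ai)
            dpda = f * A0 / Ai**2
        else:
            p = p0 + f * (1.0 - math.sqrt(A0 / Ai))
            dpda = 0.5 * f * math.sqrt(A0) / Ai**1.5
        G = p - z0_dt * Ai * u - conv_hist - p_f
        if abs(G) < tol * max(abs(p), 1.0):
            break
        dG = dpda - z0_dt * (u - c)
        step = -G / dG
        # keep area positive and step bounded
        if Ai + step <= 0.2 * A0:
            step = 0.2 * A0 - Ai + 0.5 * (Ai - 0.2 * A0)
        Ai += step
    else:
        raise RuntimeError(f"outlet Newton failed at node {b}: residual {G:.3e}")
    u = _u_of_A(net, b, Ai, W, True)
    return Ai, Ai * u


def _inlet_pressure_update(net: Network, A, Q, b: int, i: int, dt: float, p_cgs: float):
    W = _char_out(net, A, Q, b, i, dt, forward=False)
    Ai = net.area_of_pressure(p_cgs, b)
    u = _u_of_A(net, b, Ai, W, False)
    return Ai, Ai * u


def _inlet_flow_update(net: Network, A, Q, b: int, i: int, dt: float, q_target: float,
                       tol: float, maxit: int):
    W = _char_out(net, A, Q, b, i, dt, forward=False)
    Ai = float(A[b])
    f, A0 = net.f[b], net.A0[b]
    for it in range(maxit):
        u = _u_of_A(net, b, Ai, W, False)
        c = wave_speed(Ai, A0, f, net.rho, net.linear)
        G = Ai * u - q_target
        if abs(G) < tol * max(abs(q_target), 1.0):
            break
        dG = u + c
        Ai -= G / dG
        Ai = max(Ai, 0.2 * A0)
    else:
        raise RuntimeError(f"inlet Newton failed at node {b}")
    u = _u_of_A(net, b, Ai, W, False)
    return Ai, Ai * u


# ----------------------------------------------------------------------
# full periodic run
# ----------------------------------------------------------------------

@dataclass
class RunResult:
    """Converged last cycle of a network run (coarse-sampled)."""

    config: Config
    t: np.ndarray                     # sample times within the cycle, s
    A: np.ndarray                     # (n_nodes, n_samples), cm^2
    Q: np.ndarray                     # cm^3 s^-1
    P: np.ndarray                     # mmHg
    grids: Dict[str, VesselGrid]
    spectra: Dict[str, ImpedanceSpectrum]
    heart: HeartDrive
    inlet_scale: float
    coronary_fraction: float
    cycles: int
    convergence: List[float]
    junction_residual: float
    volume_in: Dict[str, float] = field(default_factory=dict)
    volume_out: Dict[str, float] = field(default_factory=dict)
    net: Optional[Network] = None

    def _station(self, vessel: str, station) -> int:
        g = self.grids[vessel]
        if station == "mid":
            return g.mid
        if station == "prox":
            return g.start
        if station == "dist":
            return g.stop - 1
        k = int(station)
        if not 0 <= k < g.n:
            raise IndexError(f"station {station} outside vessel {vessel}")
        return g.start + k

    def p(self, vessel: str, station="mid") -> np.ndarray:
        """Pressure time series (mmHg)."""
        return self.P[self._station(vessel, station)]

    def q(self, vessel: str, station="mid") -> np.ndarray:
        return self.Q[self._station(vessel, station)]

    def area(self, vessel: str, station="mid") -> np.ndarray:
        return self.A[self._station(vessel, station)]

    def u(self, vessel: str, station="mid") -> np.ndarray:
        k = self._station(vessel, station)
        return self.Q[k] / self.A[k]

    def mass_balance(self, vessel: str) -> float:
        """|net volume gain per cycle| / throughput for one vessel.

        Uses the half-step interface fluxes through which the scheme
        conserves volume; at periodicity the in/out integrals balance.
        """
        net_gain = abs(self.volume_in[vessel] - self.volume_out[vessel])
        dt = self.t[1] - self.t[0]
        g = self.grids[vessel]
        through = float(np.sum(np.abs(self.Q[g.start])) * dt)
        return net_gain / max(through, 1e-30)

    def to_frame(self, vessel: str, station="mid"):
        import pandas as pd

        k = self._station(vessel, station)
        g = self.grids[vessel]
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.net.x[k] if self.net else np.nan,
                "p_mmHg": self.P[k],
                "q_ml_s": self.Q[k],
                "u_cm_s": self.Q[k] / self.A[k],
                "A_cm2": self.A[k],
            }
        )


def build_default_network(cfg: Optional[Config] = None,
                          path=None) -> Tuple[Network, Config]:
    """Measured-geometry network with the trifurcation split."""
    cfg = cfg or Config.default()
    tree = split_trifurcation(load_vessel_table(path), cfg.trifurcation)
    return Network(tree, cfg), cfg


def _root_thevenin(net: Network, spectra, pf_cgs: Dict[str, np.ndarray], root: str):
    """Thevenin reduction of one root tree's DC (Poiseuille) network.

    Each terminal bed is its DC resistance in series with its (possibly
    time-varying) feedback-pressure source; large vessels contribute
    their tapered Poiseuille resistance.  Returns (R_root, p_source)
    where p_source has the shape of the feedback arrays.
    """
    mu = net.mu

    def vessel_R(name):
        g = net.grids[name]
        r0 = net.r0[g.start : g.stop]
        return float(np.trapezoid(8.0 * mu / (math.pi * r0**4), dx=g.dx))

    def thevenin(name):
        seg = net.tree[name]
        if seg.terminal:
            return vessel_R(name) + spectra[name].z_dc, pf_cgs[name]
        (r1, p1), (r2, p2) = thevenin(seg.daughters[0]), thevenin(seg.daughters[1])
        g1, g2 = 1.0 / r1, 1.0 / r2
        r_par = 1.0 / (g1 + g2)
        p_par = (p1 * g1 + p2 * g2) * r_par
        return vessel_R(name) + r_par, p_par

    return thevenin(root)


def _dc_resistance_estimate(net: Network, spectra, pf_mean_cgs, pa_mean_cgs):
    """Mean coronary inflow (and its pressure derivative) of the DC network."""
    q = 0.0
    dq_dp = 0.0
    for root in net.roots:
        R, pb = _root_thevenin(net, spectra, pf_mean_cgs, root)
        q += (pa_mean_cgs - pb) / R
        dq_dp += 1.0 / R
    return q, dq_dp


def run_to_periodic(
    tree: Optional[CoronaryTree] = None,
    cfg: Optional[Config] = None,
    *,
    calibrate: bool = True,
    inlet_scale: Optional[float] = None,
    network: Optional[Network] = None,
    warm: Optional[Tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
    progress: bool = False,
    force_python: bool = False,
) -> RunResult:
    """Integrate cardiac cycles until the pressure field is periodic.

    Convergence: max over nodes of the L-inf difference of pressure
    between consecutive cycles below ``numerics.conv_tol_mmhg``.  With
    ``calibrate`` the inlet scale factor is adjusted (secant iteration,
    warm-started) until mean coronary inflow is ``inlet.coronary_fraction``
    of cardiac output within ``inlet.fraction_tol``.
    """
    cfg = cfg or Config.default()
    if network is None:
        if tree is None:
            tree = split_trifurcation(load_vessel_table(), cfg.trifurcation)
        network = Network(tree, cfg)
    net = network
    num = cfg.numerics
    t_c = cfg.ventricle_left.t_c
    n_samples = num.n_samples

    # --- heart and reference pressures ---------------------------------
    drive = inlet_waveform(cfg, n_samples)
    net.set_reference_pressure(drive.p0_ref_left, drive.p0_ref_right)

    # --- terminal bed impedances ----------------------------------------
    spectra: Dict[str, ImpedanceSpectrum] = {}
    for name in net.terminals:
        spectra[name] = root_impedance(
            net.tree[name].r_dist, cfg.tree, cfg.fluid, cfg.wall, t_c, n_samples
        )

    # --- time step: integer substeps per kernel sample ------------------
    c0 = net.c0()
    dt_cfl = num.cfl * float(np.min(net.dxn / (1.15 * c0)))
    dtau = t_c / n_samples
    m_sub = max(1, int(math.ceil(dtau / dt_cfl)))
    steps = n_samples * m_sub
    dt = t_c / steps

    # --- fine-resolution drive waveforms --------------------------------
    fine = inlet_waveform(cfg, steps)
    p_in_fine = fine.p_aorta * MMHG
    term_idx = {nm: net.grids[nm].stop - 1 for nm in net.terminals}
    pf_fine = {}
    pf_mean = {}
    for nm in net.terminals:
        loc = net.tree[nm].supply_location
        pf = feedback_pressure(fine.t, nm, cfg.feedback, loc, fine.pv_left, fine.pv_right)
        pf_fine[nm] = np.asarray(pf) * MMHG
        pf_mean[nm] = float(np.mean(pf)) * MMHG

    kernels = np.stack([spectra[nm].kernel for nm in net.terminals])
    z0_dt = kernels[:, 0] * dtau
    ker_rest = kernels[:, 1:]  # (n_term, n_samples-1)

    # --- inlet scale ----------------------------------------------------
    if inlet_scale is None:
        if calibrate:
            pa_mean = float(np.mean(fine.p_aorta)) * MMHG
            q_dc, dq_dp = _dc_resistance_estimate(net, spectra, pf_mean, pa_mean)
            target = drive.target_coronary_flow
            scale = 1.0 + (target - q_dc) / (dq_dp * pa_mean)
        else:
            scale = cfg.inlet.scale
    else:
        scale = inlet_scale

    # --- state ----------------------------------------------------------
    if warm is not None:
        A, Q, qhist = (w.copy() for w in warm)
        hist_ready = True
    else:
        A = net.A0.copy()
        Q = np.zeros(net.n_nodes)
        qhist = np.zeros((len(net.terminals), steps))
        hist_ready = False
        log.info("first cycle: outlet history zero-padded")

    root_in = [net.grids[r].start for r in net.roots]
    root_nb = [k + 1 for k in root_in]
    conv_hist_idx = (np.arange(1, n_samples) * m_sub)  # offsets in fine steps

    flow_mode = cfg.inlet.mode == "flow"
    q_in_fine = None
    if flow_mode:
        # prescribed coronary inflow per root from the lumped estimate
        # q_r(t) = (p_a(t) - p_bed,r(t)) / R_r, with p_bed the
        # conductance-weighted (time-varying) feedback pressure of the
        # root's beds; scaled so total mean inflow is the target fraction
        pa_fine_cgs = fine.p_aorta * MMHG
        q_raw = []
        for r in net.roots:
            R_r, pb_r = _root_thevenin(net, spectra, pf_fine, r)
            q_raw.append((pa_fine_cgs - pb_r) / R_r)
        q_raw = np.asarray(q_raw)
        scale_q = drive.target_coronary_flow / float(np.mean(q_raw.sum(axis=0)))
        if inlet_scale is not None:
            scale_q = inlet_scale
        q_in_fine = scale_q * q_raw
        scale = scale_q

    results_prev = None
    convergence: List[float] = []
    worst_res = 0.0
    n_cycles = 0
    A_coarse = np.empty((net.n_nodes, n_samples))
    Q_coarse = np.empty_like(A_coarse)
    vol_in = np.zeros(len(net._order))
    vol_out = np.zeros(len(net._order))

    # --- compiled fast path ---------------------------------------------
    from . import _kernel

    use_kernel = _kernel.HAVE_NUMBA and not force_python
    if use_kernel:
        jn_nodes = np.array(
            [[j.p_b, j.p_i, j.d1_b, j.d1_i, j.d2_b, j.d2_i] for j in net.junctions],
            dtype=np.int64,
        ).reshape(-1, 6)
        term_b_arr = np.array([term_idx[nm] for nm in net.terminals], dtype=np.int64)
        pf_mat = np.stack([pf_fine[nm] for nm in net.terminals])
        root_b_arr = np.array(root_in, dtype=np.int64)
        conv_off = conv_hist_idx.astype(np.int64)
        q_in_mat = (
            q_in_fine if flow_mode else np.zeros((len(root_in), steps))
        )
        scr = dict(
            An=np.empty(net.n_nodes), Qn=np.empty(net.n_nodes),
            F1=np.empty(net.n_nodes), F2=np.empty(net.n_nodes), S=np.empty(net.n_nodes),
            Ah=np.empty(net.n_if), Qh=np.empty(net.n_if),
            F1h=np.empty(net.n_if), F2h=np.empty(net.n_if), Sh=np.empty(net.n_if),
        )
        _status_msg = {
            _kernel.NEGATIVE_AREA: "negative area",
            _kernel.CFL_VIOLATION: "CFL violation",
            _kernel.NEWTON_FAIL_JUNCTION: "junction Newton failed",
            _kernel.NEWTON_FAIL_OUTLET: "outlet Newton failed",
            _kernel.NEWTON_FAIL_INLET: "inlet Newton failed",
        }

        def one_cycle(A, Q, qhist, scale):
            nonlocal worst_res
            vol_in[:] = 0.0
            vol_out[:] = 0.0
            status, node, res = _kernel.run_cycle(
                A, Q, scr["An"], scr["Qn"], qhist,
                steps, m_sub, dt, dtau,
                net.A0, net.f, net.fp, net.dr0dx, net.r0, net.dxn, net.p0,
                net.ifL, net.ifR, net.A0h, net.fh, net.fph, net.dr0dxh,
                net.r0h, net.dxh,
                net.int_nodes, net.int_ifL, net.int_ifR,
                net.rho, net.mu, net.delta, net.linear, net.kappa,
                jn_nodes,
                term_b_arr, z0_dt, np.ascontiguousarray(ker_rest), pf_mat, conv_off,
                root_b_arr, flow_mode, p_in_fine,
                q_in_mat, scale,
                num.junction_tol, num.max_newton,
                A_coarse, Q_coarse,
                net.vif_first, net.vif_last, vol_in, vol_out,
                scr["F1"], scr["F2"], scr["S"],
                scr["Ah"], scr["Qh"], scr["F1h"], scr["F2h"], scr["Sh"],
            )
            if status != _kernel.OK:
                raise FloatingPointError(
                    f"{_status_msg[status]} at node {node} (x={net.x[node]:.3f})"
                )
            worst_res = max(worst_res, res)
            return A, Q

        run_one_cycle = one_cycle
    else:
        run_one_cycle = None  # defined below

    def one_cycle_py(A, Q, qhist, scale):
        nonlocal worst_res
        vol_in[:] = 0.0
        vol_out[:] = 0.0
        for n in range(steps):
            n1 = (n + 1) % steps  # index of the new time level in the drive
            # boundary data extracted from state at t_n inside the closures
            An, Qn, F1h = lax_wendroff_step(net, A, Q, dt, return_flux=True)
            vol_in[:] += F1h[net.vif_first] * dt
            vol_out[:] += F1h[net.vif_last] * dt
            # inlets
            for ridx, (b, i) in enumerate(zip(root_in, root_nb)):
                if flow_mode:
                    Ab, Qb = _inlet_flow_update(
                        net, A, Q, b, i, dt, q_in_fine[ridx, n1], 1e-12, num.max_newton
                    )
                else:
                    Ab, Qb = _inlet_pressure_update(
                        net, A, Q, b, i, dt, scale * p_in_fine[n1]
                    )
                An[b], Qn[b] = Ab, Qb
            # junctions
            for jn in net.junctions:
                out, res = junction_solve(net, A, Q, jn, dt, num.junction_tol, num.max_newton)
                (Ap, qp), (A1, q1), (A2, q2) = out
                An[jn.p_b], Qn[jn.p_b] = Ap, qp
                An[jn.d1_b], Qn[jn.d1_b] = A1, q1
                An[jn.d2_b], Qn[jn.d2_b] = A2, q2
                worst_res = max(worst_res, res)
            # outlets
            idx = (n - conv_hist_idx) % steps
            qh = qhist[:, idx]
            conv = dtau * np.einsum("tj,tj->t", ker_rest, qh)
            for k, nm in enumerate(net.terminals):
                b = term_idx[nm]
                Ab, Qb = outlet_update(
                    net, A, Q, b, b - 1, dt,
                    z0_dt[k], conv[k], pf_fine[nm][n1],
                    1e-12, num.max_newton,
                )
                An[b], Qn[b] = Ab, Qb
            A, Q = An, Qn
            qhist[:, n] = Q[[term_idx[nm] for nm in net.terminals]]
            if n % m_sub == 0:
                k = n // m_sub
                A_coarse[:, k] = A
                Q_coarse[:, k] = Q
        return A, Q

    if run_one_cycle is None:
        run_one_cycle = one_cycle_py

    max_change = np.inf
    while n_cycles < num.max_cycles and max_change > num.conv_tol_mmhg:
        A, Q = run_one_cycle(A, Q, qhist, scale)
        n_cycles += 1
        P_now = net.pressure(A_coarse) / MMHG
        if results_prev is not None:
            max_change = float(np.max(np.abs(P_now - results_prev)))
        convergence.append(max_change if np.isfinite(max_change) else float("nan"))
        results_prev = P_now.copy()
        if progress:
            log.info("cycle %d: max |dp| = %s mmHg", n_cycles, f"{max_change:.4f}")
    if max_change > num.conv_tol_mmhg:
        raise RuntimeError(
            f"no periodic convergence in {num.max_cycles} cycles "
            f"(last change {max_change:.3f} mmHg)"
        )

    # --- calibration loop ------------------------------------------------
    def fraction(Q_coarse):
        q_in = sum(Q_coarse[net.grids[r].start] for r in net.roots)
        return float(np.mean(q_in)) / drive.cardiac_output

    frac = fraction(Q_coarse)
    if calibrate and not flow_mode:
        target = cfg.inlet.coronary_fraction
        tol = cfg.inlet.fraction_tol
        s_hist = [(scale, frac)]
        tries = 0
        while abs(frac - target) > tol and tries < 6:
            if len(s_hist) >= 2 and abs(s_hist[-1][1] - s_hist[-2][1]) > 1e-12:
                (sa, fa), (sb, fb) = s_hist[-2], s_hist[-1]
                scale = sb + (target - fb) * (sb - sa) / (fb - fa)
            else:
                scale = s_hist[-1][0] * (1.0 + (target - frac) / max(frac, 1e-6))
            # warm-started re-run
            results_prev = None
            max_change = np.inf
            cycles_inner = 0
            while cycles_inner < num.max_cycles and max_change > num.conv_tol_mmhg:
                A, Q = run_one_cycle(A, Q, qhist, scale)
                cycles_inner += 1
                n_cycles += 1
                P_now = net.pressure(A_coarse) / MMHG
                if results_prev is not None:
                    max_change = float(np.max(np.abs(P_now - results_prev)))
                convergence.append(max_change if np.isfinite(max_change) else float("nan"))
                results_prev = P_now.copy()
            frac = fraction(Q_coarse)
            s_hist.append((scale, frac))
            tries += 1
            if progress:
                log.info("calibration: scale %.4f -> fraction %.4f", scale, frac)
        if abs(frac - target) > tol:
            raise RuntimeError(
                f"inlet calibration did not converge: fraction {frac:.4f} vs target {target}"
            )

    # --- polish: tighten periodicity of the reported cycle ---------------
    # (per-cycle volume storage scales with the residual cycle-to-cycle
    # pressure drift; a few extra cycles make the mass budget close)
    extra = 0
    while max_change > num.polish_tol_mmhg and extra < 10:
        A, Q = run_one_cycle(A, Q, qhist, scale)
        n_cycles += 1
        extra += 1
        P_now = net.pressure(A_coarse) / MMHG
        max_change = float(np.max(np.abs(P_now - results_prev)))
        convergence.append(max_change)
        results_prev = P_now.copy()
    frac = fraction(Q_coarse)

    t = np.arange(n_samples) * dtau
    P_final = net.pressure(A_coarse) / MMHG
    return RunResult(
        config=cfg,
        t=t,
        A=A_coarse.copy(),
        Q=Q_coarse.copy(),
        P=P_final,
        grids=net.grids,
        spectra=spectra,
        heart=drive,
        inlet_scale=scale,
        coronary_fraction=frac,
        cycles=n_cycles,
        convergence=convergence,
        junction_residual=worst_res,
        volume_in={nm: float(vol_in[k]) for k, nm in enumerate(net._order)},
        volume_out={nm: float(vol_out[k]) for k, nm in enumerate(net._order)},
        net=net,
    )
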