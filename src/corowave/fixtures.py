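"""Small synthetic inputs: explicit toy trees and analytic waveforms.

These generators make every stage testable in milliseconds: explicit
vessel-by-vessel toy trees serve as brute-force oracles for the
memoized structured-tree impedance, and constructed pressure/velocity
waveforms with known forward/backward content exercise the wave
decomposition against the water-hammer ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .config import MMHG, FluidParams, StructuredTreeParams, WallLaw
from .geometry import CoronaryTree, VesselSegment
from .impedance import (
    compliance,
    poiseuille_resistance,
    transmission_line_impedance,
    womersley_factor,
)

__all__ = [
    "ToyTreeSpec",
    "ToyVessel",
    "make_toy_tree",
    "brute_force_impedance",
    "brute_force_dc_resistance",
    "make_synthetic_waveforms",
    "single_vessel_tree",
]


@dataclass
class ToyVessel:
    """One explicitly enumerated vessel of a toy structured tree."""

    radius: float
    length: float
    children: List["ToyVessel"] = field(default_factory=list)

    def count(self) -> int:
        return 1 + sum(c.count() for c in self.children)

    def leaves(self) -> int:
        if not self.children:
            return 1
        return sum(c.leaves() for c in self.children)


@dataclass
class ToyTreeSpec:
    """Explicit small structured tree (brute-force oracle scale)."""

    r_root: float = 0.05
    alpha: float = 0.9
    beta: float = 0.6
    l_rr: float = 25.0
    r_min: float = 0.01
    generations: Optional[int] = None   # optional hard depth cap
    perturb: float = 0.0                # relative radius jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations is not None and self.generations > 6:
            raise ValueError("toy trees are limited to 6 generations")


def make_toy_tree(spec: ToyTreeSpec) -> ToyVessel:
    """Enumerate a structured tree vessel-by-vessel (no memoization).

    Uses the same termination rule as the production lattice: a daughter
    below ``r_min`` is not created.  ``generations`` optionally caps the
    depth; ``perturb`` applies seeded multiplicative radius jitter
    (reproducible; jittered trees are for loaders/plumbing, not for
    comparison with the self-similar recursion).
    """
    rng = np.random.default_rng(spec.seed)

    def build(r_nominal: float, depth: int) -> Optional[ToyVessel]:
        if r_nominal < spec.r_min:
            return None
        r = r_nominal
        if spec.perturb > 0.0:
            r = r_nominal * (1.0 + spec.perturb * rng.standard_normal())
        v = ToyVessel(radius=r, length=spec.l_rr * r)
        if spec.generations is None or depth < spec.generations:
            for ratio in (spec.alpha, spec.beta):
                child = build(r_nominal * ratio, depth + 1)
                if child is not None:
                    v.children.append(child)
        return v

    root = build(spec.r_root, 0)
    if root is None:
        raise ValueError("root radius below r_min: empty toy tree")
    return root


def brute_force_impedance(
    vessel: ToyVessel,
    omega,
    fluid: FluidParams,
    wall: WallLaw,
    z_terminal: float = 0.0,
):
    """Root impedance of an explicit toy tree, vessel by vessel.

    Independent of the lattice recursion: plain structural recursion
    combining children in parallel and propagating through each
    transmission line (Poiseuille resistance at omega = 0).
    """
    omega = np.asarray(omega, dtype=float)
    dc = omega == 0.0

    def z_root(v: ToyVessel):
        if v.children:
            inv = 0.0
            for c in v.children:
                inv = inv + 1.0 / z_root(c)
            z_load = 1.0 / inv
        else:
            z_load = np.full(omega.shape, complex(z_terminal))
        a0 = np.pi * v.radius**2
        cmp_ = compliance(v.radius, wall)
        out = np.empty(omega.shape, dtype=complex)
        if np.any(~dc):
            om = omega[~dc]
            k = womersley_factor(om, v.radius, fluid)
            c = np.sqrt(a0 * k / (fluid.rho * cmp_))
            g = np.sqrt(cmp_ * a0 * k / fluid.rho)
            zl = z_load[~dc] if np.ndim(z_load) else z_load
            out[~dc] = transmission_line_impedance(zl, v.length, c, g, om)
        if np.any(dc):
            zl_dc = (z_load[dc].real if np.ndim(z_load) else z_load.real)
            out[dc] = zl_dc + poiseuille_resistance(v.radius, v.length, fluid)
        return out

    return z_root(vessel)


def brute_force_dc_resistance(vessel: ToyVessel, fluid: FluidParams,
                              z_terminal: float = 0.0) -> float:
    """Series/parallel Poiseuille reduction of an explicit toy tree."""
    if vessel.children:
        inv = sum(1.0 / brute_force_dc_resistance(c, fluid, z_terminal)
                  for c in vessel.children)
        load = 1.0 / inv
    else:
        load = z_terminal
        if load == 0.0:
            load = 0.0
    return load + poiseuille_resistance(vessel.radius, vessel.length, fluid)


def make_synthetic_waveforms(
    kind: str,
    n: int,
    seed: int = 0,
    rho: float = 1.055,
    c_p: float = 800.0,
    backward_fraction: float = 0.35,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Pressure/velocity series with analytically known wave content.

    ``forward_pulse`` and ``backward_pulse`` are single compression
    pulses obeying the water-hammer relation dp = +- rho c_p du exactly;
    ``mixed`` superposes a forward pulse and a backward pulse with a
    known energy split.  Returns (p_mmhg, u_cm_s, truth) where ``truth``
    holds the construction (component series and rho c_p).
    """
    if n < 16:
        raise ValueError("need at least 16 samples")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    width = 0.06 * (1.0 + 0.1 * rng.random())

    def bump(center):
        return np.exp(-((t - center) / width) ** 2)

    rc = rho * c_p
    p_fwd_cgs = 10.0 * MMHG * bump(0.3)
    p_bwd_cgs = backward_fraction * 10.0 * MMHG * bump(0.6)
    if kind == "forward_pulse":
        p_cgs = p_fwd_cgs
        u = p_fwd_cgs / rc
    elif kind == "backward_pulse":
        p_cgs = p_bwd_cgs
        u = -p_bwd_cgs / rc
    elif kind == "mixed":
        p_cgs = p_fwd_cgs + p_bwd_cgs
        u = (p_fwd_cgs - p_bwd_cgs) / rc
    else:
        raise ValueError(f"unknown waveform kind {kind!r}")
    truth = {
        "rho_c": rc,
        "p_forward_mmhg": p_fwd_cgs / MMHG,
        "p_backward_mmhg": p_bwd_cgs / MMHG,
        "c_p": c_p,
    }
    return p_cgs / MMHG, u, truth


def single_vessel_tree(length: float = 10.0, r_prox: float = 0.15,
                       r_dist: float = 0.15, name: str = "V",
                       supply_location: str = "left_ventricle") -> CoronaryTree:
    """One-segment network for solver unit tests."""
    seg = VesselSegment(name=name, length=length, r_prox=r_prox, r_dist=r_dist,
                        supply_location=supply_location)
    return CoronaryTree(segments={name: seg}, roots=[name])
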