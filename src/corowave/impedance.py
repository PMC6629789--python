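"""Frequency-domain root impedance of structured-tree vascular beds.

Each terminal large artery is closed by the input impedance Z(0, omega)
of its vascular bed.  Within the bed, pulsatile flow in each small
vessel obeys the linearized (Womersley) momentum and continuity
equations, which reduce to a lossless transmission line of complex wave
speed c and characteristic admittance g = sqrt(C A0 K / rho).  Sibling
impedances combine in parallel at bifurcations and propagate to the
vessel inlet through the transmission-line transform; self-similarity
lets the recursion run over the (i, j) radius lattice with memoization
instead of enumerating the (potentially millions of) vessels.

Conventions: time dependence e^{+i omega t} (matching numpy's inverse
FFT), so the line transform is

    Z(0) = (i g^-1 sin(theta) + Z_l cos(theta)) / (cos(theta) + i g Z_l sin(theta)),

theta = omega l / c.  At omega = 0 the transform has a removable
singularity whose limit is the Poiseuille resistance 8 mu l / (pi r^4);
the DC value is accumulated through the same recursion on that branch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import special

from .config import FluidParams, StructuredTreeParams, WallLaw
from .geometry import structured_tree_radii

__all__ = [
    "womersley_factor",
    "compliance",
    "poiseuille_resistance",
    "transmission_line_impedance",
    "root_impedance",
    "impedance_to_kernel",
    "ImpedanceSpectrum",
]

_I32 = 1j ** 1.5  # i^{3/2} = e^{3 i pi / 4}


def womersley_factor(omega, r0: float, fluid: FluidParams):
    """Viscous factor K = 1 - F_J(w0) of linearized pulsatile flow.

    w0 = r0 sqrt(omega rho / mu) is the Womersley number and
    F_J = 2 J1(i^{3/2} w0) / (i^{3/2} w0 J0(i^{3/2} w0)).  K -> 1 in the
    inviscid (large w0) limit and K ~ i w0^2 / 8 -> 0 in the viscous
    limit.  omega = 0 is handled by the Poiseuille branch of
    :func:`root_impedance`, not here.  Vectorized over omega.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be non-negative")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    w0 = r0 * np.sqrt(omega * fluid.rho / fluid.mu)
    z = _I32 * w0
    # exponentially scaled Bessel functions share the same scaling factor,
    # so their ratio is exact and overflow-free for large |z|
    with np.errstate(invalid="ignore", divide="ignore"):
        fj = 2.0 * special.jve(1, z) / (z * special.jve(0, z))
    fj = np.where(w0 == 0.0, 1.0, fj)
    return 1.0 - fj


def compliance(r0: float, wall: WallLaw) -> float:
    """Small-vessel compliance per unit length C = 3 A0 r0 / (2 Eh).

    With A0 = pi r0^2 and the stiffness law Eh/r0 = k1 e^{k2 r0} + k3,
    C = 3 pi r0^3 / (2 Eh) = (3/2) A0 / (Eh/r0).
    """
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    a0 = np.pi * r0 * r0
    return 1.5 * a0 / float(wall.eh_over_r0(r0))


def poiseuille_resistance(r0: float, length: float, fluid: FluidParams) -> float:
    """DC resistance 8 mu l / (pi r0^4) of a rigid cylindrical vessel."""
    return 8.0 * fluid.mu * length / (np.pi * r0**4)


def transmission_line_impedance(z_end, length: float, c, g, omega):
    """Input impedance of a lossless line of speed c loaded by ``z_end``.

    ``g`` is the characteristic admittance sqrt(C A0 K / rho); a matched
    load z_end = 1/g is invariant under the transform.  Vectorized over
    omega (c, g, z_end may be arrays of the same shape).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    theta = np.asarray(omega) * length / c
    s, co = np.sin(theta), np.cos(theta)
    den = co + 1j * g * z_end * s
    if np.any(np.abs(den) < 1e-12 * (1.0 + np.abs(g * z_end * s))):
        bad = np.argmin(np.abs(np.atleast_1d(den)))
        w = np.atleast_1d(np.broadcast_to(omega, np.shape(den)))[bad]
        raise ZeroDivisionError(
            f"transmission line resonance: omega={w}, l={length}"
        )
    return (1j * s / g + z_end * co) / den


@dataclass
class ImpedanceSpectrum:
    """Root impedance of a vascular bed on the harmonic grid.

    ``omega`` holds angular frequencies 2 pi k / T for k = 0 .. n/2;
    ``Z`` the complex impedance at those harmonics (Z[0] real, the DC
    resistance); ``kernel`` the real time-domain sequence z(t_i) over one
    period such that p(t) = sum_tau z(tau) q(t - tau) dt.
    """

    period: float
    omega: np.ndarray
    Z: np.ndarray
    kernel: Optional[np.ndarray] = None

    @property
    def n_samples(self) -> int:
        return 2 * (len(self.omega) - 1)

    @property
    def dt(self) -> float:
        return self.period / self.n_samples

    @property
    def z_dc(self) -> float:
        return float(self.Z[0].real)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "harmonic_index": np.arange(len(self.omega)),
                "omega": self.omega,
                "Re_Z": self.Z.real,
                "Im_Z": self.Z.imag,
            }
        )


def root_impedance(
    r_root: float,
    tree: StructuredTreeParams,
    fluid: FluidParams,
    wall: WallLaw,
    period: float,
    n_samples: int,
) -> ImpedanceSpectrum:
    """Root impedance spectrum of the structured tree below ``r_root``.

    Harmonics 0 .. n_samples/2 of the cardiac frequency 2 pi / period.
    The recursion runs leaf-to-root over the (i, j) radius lattice: a
    vessel's load is the parallel combination of the daughters present in
    the lattice (daughters thinner than r_min are never created), or the
    terminal load for lattice leaves; the load is then propagated through
    the vessel's transmission line (Poiseuille resistance in series at
    DC).  Memoization on (i, j) is exact by self-similarity.
    """
    if r_root <= 0:
        raise ValueError(f"non-positive root radius {r_root}")
    nh = n_samples // 2 + 1
    omega = 2.0 * np.pi * np.arange(nh) / period
    radii = structured_tree_radii(r_root, tree)
    if not radii:
        raise ValueError(
            f"root radius {r_root} below minimum radius {tree.r_min}: empty tree"
        )

    # per-radius line properties, vectorized over the nonzero harmonics
    om = omega[1:]
    cache: Dict[Tuple[int, int], np.ndarray] = {}
    cache_dc: Dict[Tuple[int, int], float] = {}

    def vessel_z(ij: Tuple[int, int]) -> np.ndarray:
        if ij in cache:
            return cache[ij]
        r = radii[ij]
        i, j = ij
        d1, d2 = (i + 1, j), (i, j + 1)
        have1, have2 = d1 in radii, d2 in radii
        if have1 and have2:
            za, zb = vessel_z(d1), vessel_z(d2)
            z_load = za * zb / (za + zb)
            z_load_dc = _parallel_dc(cache_dc[d1], cache_dc[d2])
        elif have1:
            z_load = vessel_z(d1)
            z_load_dc = cache_dc[d1]
        elif have2:
            z_load = vessel_z(d2)
            z_load_dc = cache_dc[d2]
        else:
            z_load = np.full(om.shape, complex(tree.z_terminal))
            z_load_dc = tree.z_terminal
        length = tree.l_rr * r
        a0 = np.pi * r * r
        cmp_ = compliance(r, wall)
        k = womersley_factor(om, r, fluid)
        c = np.sqrt(a0 * k / (fluid.rho * cmp_))
        g = np.sqrt(cmp_ * a0 * k / fluid.rho)
        z0 = transmission_line_impedance(z_load, length, c, g, om)
        cache[ij] = z0
        cache_dc[ij] = z_load_dc + poiseuille_resistance(r, length, fluid)
        return z0

    z_ac = vessel_z((0, 0))
    z = np.empty(nh, dtype=complex)
    z[0] = cache_dc[(0, 0)]
    z[1:] = z_ac
    spec = ImpedanceSpectrum(period=period, omega=omega, Z=z)
    spec.kernel = impedance_to_kernel(spec, n_samples)
    return spec


def _parallel_dc(za: float, zb: float) -> float:
    if za == 0.0 or zb == 0.0:
        return 0.0
    return za * zb / (za + zb)


def impedance_to_kernel(spectrum: ImpedanceSpectrum, n_samples: int) -> np.ndarray:
    """Real periodic convolution kernel z(t_i), i = 0 .. n_samples - 1.

    Inverse DFT with conjugate (Hermitian) symmetry of the one-sided
    spectrum; normalized so that p(t_n) = sum_j z_j q(t_n - t_j) dt with
    dt = period / n_samples, hence mean(z) * period = Z(0) (DC
    consistency).
    """
    nh = n_samples // 2 + 1
    if len(spectrum.Z) < nh:
        raise ValueError(
            f"spectrum has {len(spectrum.Z)} harmonics; need {nh} for {n_samples} samples"
        )
    z_half = np.array(spectrum.Z[:nh], dtype=complex)
    # rfft layout: DC and (for even n) Nyquist bins must be real
    z_half[0] = z_half[0].real
    z_half[-1] = z_half[-1].real
    kernel = np.fft.irfft(z_half, n=n_samples) * n_samples / spectrum.period
    return kernel
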