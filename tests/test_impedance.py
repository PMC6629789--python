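"""Vascular-bed impedance: Womersley factor, line transform, recursion, kernel."""

import math

import numpy as np
import pytest

from corowave.config import Config, FluidParams, StructuredTreeParams, WallLaw
from corowave.fixtures import (
    ToyTreeSpec,
    brute_force_dc_resistance,
    brute_force_impedance,
    make_toy_tree,
)
from corowave.geometry import alpha_beta_from_exponent, load_vessel_table, split_trifurcation
from corowave.impedance import (
    ImpedanceSpectrum,
    compliance,
    impedance_to_kernel,
    poiseuille_resistance,
    root_impedance,
    transmission_line_impedance,
    womersley_factor,
)

FLUID = FluidParams()
WALL = WallLaw()


def _bessel_series(order, z, terms=40):
    """Power-series Bessel J_order(z), independent of scipy."""
    total = 0.0 + 0.0j
    for k in range(terms):
        total += (-1.0) ** k * (z / 2.0) ** (2 * k + order) / (
            math.factorial(k) * math.factorial(k + order)
        )
    return total


class TestWomersleyFactor:
    def test_matches_independent_bessel_series(self):
        omega = 2.0 * math.pi / 0.9
        r0 = 0.05
        w0 = r0 * math.sqrt(omega * FLUID.rho / FLUID.mu)
        z = 1j**1.5 * w0
        fj = 2.0 * _bessel_series(1, z) / (z * _bessel_series(0, z))
        expected = 1.0 - fj
        got = complex(womersley_factor(omega, r0, FLUID))
        assert abs(got - expected) < 1e-10

    def test_viscous_limit_small_w0(self):
        # K ~ i w0^2 / 8 as w0 -> 0
        r0 = 1e-4
        omega = 1.0
        w0 = r0 * math.sqrt(omega * FLUID.rho / FLUID.mu)
        got = complex(womersley_factor(omega, r0, FLUID))
        assert got == pytest.approx(1j * w0**2 / 8.0, rel=1e-3)
        assert abs(got) < 1.0

    def test_inviscid_limit_large_w0(self):
        # w0 ~ 500: F_J ~ 2/w0 -> K within 1% of 1
        omega = 2.0 * math.pi * 2000.0
        r0 = 0.15
        got = complex(womersley_factor(omega, r0, FLUID))
        assert abs(got - 1.0) < 0.01

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            womersley_factor(-1.0, 0.05, FLUID)


class TestCompliance:
    def test_hand_evaluation(self):
        r0 = 0.05
        eh_r0 = 2e7 * math.exp(-22.5 * r0) + 8.65e5
        assert eh_r0 == pytest.approx(7.36e6, rel=1e-3)
        a0 = math.pi * r0**2
        assert compliance(r0, WALL) == pytest.approx(1.5 * a0 / eh_r0, rel=1e-12)

    def test_scaling_with_stiffness(self):
        stiff = WallLaw(k1=2 * WALL.k1, k2=WALL.k2, k3=2 * WALL.k3)
        # doubling k1 and k3 halves C (k2 unchanged keeps the exponential shape)
        assert compliance(0.05, stiff) == pytest.approx(0.5 * compliance(0.05, WALL))

    def test_large_radius_limit(self):
        # Eh/r0 -> k3 for large r0
        r0 = 2.0
        assert float(WALL.eh_over_r0(r0)) == pytest.approx(WALL.k3, rel=1e-12)


class TestTransmissionLine:
    C = 500.0 + 0.0j        # complex wave speed stand-in
    G = 2.5e-5 + 0.0j       # characteristic admittance stand-in

    def test_zero_length_limit(self):
        z_end = 3.0e4 + 1.0e3j
        z = transmission_line_impedance(z_end, 1e-9, self.C, self.G, 10.0)
        assert z == pytest.approx(z_end, rel=1e-9)

    def test_matched_load_invariant(self):
        z_end = 1.0 / self.G
        for length in (0.1, 1.0, 7.3):
            z = transmission_line_impedance(z_end, length, self.C, self.G, 20.0)
            assert z == pytest.approx(z_end, rel=1e-12)

    def test_half_wavelength_invariance(self):
        omega = 40.0
        length = math.pi * abs(self.C) / omega     # omega l / c = pi
        z_end = 5.0e4 - 2.0e3j
        z = transmission_line_impedance(z_end, length, self.C, self.G, omega)
        assert z == pytest.approx(z_end, rel=1e-10)

    def test_resonance_raises(self):
        omega = 40.0
        length = 0.5 * math.pi * abs(self.C) / omega   # quarter wave, open end
        with pytest.raises(ZeroDivisionError, match="resonance"):
            transmission_line_impedance(0.0 + 0.0j, length, self.C, self.G, omega)


class TestRootImpedance:
    def test_single_leaf_dc_is_poiseuille(self):
        # smallest vessel: r0 = 10 um, l = l_rr r0
        r0, lrr = 1e-3, 25.0
        z = poiseuille_resistance(r0, lrr * r0, FLUID)
        assert z == pytest.approx(8 * FLUID.mu * lrr * r0 / (math.pi * r0**4), rel=1e-12)
        assert z == pytest.approx(2.99e8, rel=1e-2)
        p = StructuredTreeParams(r_min=9e-4, alpha=0.5, beta=0.4, l_rr=lrr)
        spec = root_impedance(r0, p, FLUID, WALL, 0.9, 16)
        assert spec.z_dc == pytest.approx(z, rel=1e-12)

    def test_symmetric_parent_dc(self):
        # alpha = beta: parent Z_DC = own resistance + half the daughter's
        p = StructuredTreeParams(alpha=0.7, beta=0.7 - 1e-13, r_min=0.02, l_rr=10.0)
        spec_parent = root_impedance(0.05, p, FLUID, WALL, 0.9, 16)
        spec_d = root_impedance(0.05 * 0.7, p, FLUID, WALL, 0.9, 16)
        own = poiseuille_resistance(0.05, 10.0 * 0.05, FLUID)
        assert spec_parent.z_dc == pytest.approx(own + 0.5 * spec_d.z_dc, rel=1e-6)

    def test_memoized_equals_brute_force(self):
        p = StructuredTreeParams(alpha=0.9, beta=0.6, r_min=0.01, l_rr=25.0)
        toy = make_toy_tree(ToyTreeSpec(r_root=0.05, r_min=0.01))
        spec = root_impedance(0.05, p, FLUID, WALL, 0.9, 64)
        bf = brute_force_impedance(toy, spec.omega, FLUID, WALL)
        assert np.max(np.abs(spec.Z - bf) / np.abs(bf)) < 1e-12

    def test_dc_equals_poiseuille_network_reduction(self):
        p = StructuredTreeParams(alpha=0.85, beta=0.55, r_min=0.008, l_rr=20.0)
        toy = make_toy_tree(ToyTreeSpec(r_root=0.04, alpha=0.85, beta=0.55,
                                        r_min=0.008, l_rr=20.0))
        spec = root_impedance(0.04, p, FLUID, WALL, 0.9, 16)
        assert spec.z_dc == pytest.approx(brute_force_dc_resistance(toy, FLUID), rel=1e-12)

    def test_rarefaction_raises_dc_impedance_of_every_bed(self):
        cfg = Config.default()
        tree = split_trifurcation(load_vessel_table(), cfg.trifurcation)
        a, b = alpha_beta_from_exponent(2.4, cfg.tree.gamma)
        rare = StructuredTreeParams(alpha=a, beta=b, xi=2.4)
        for name in tree.terminals:
            r = tree[name].r_dist
            z0 = root_impedance(r, cfg.tree, cfg.fluid, cfg.wall, 0.9, 16).z_dc
            z1 = root_impedance(r, rare, cfg.fluid, cfg.wall, 0.9, 16).z_dc
            assert z1 > z0

    def test_empty_tree_flagged(self):
        p = StructuredTreeParams(r_min=0.05)
        with pytest.raises(ValueError, match="empty tree"):
            root_impedance(0.01, p, FLUID, WALL, 0.9, 16)


class TestKernel:
    def _spectrum(self, n, period=0.9):
        p = StructuredTreeParams(r_min=0.01)
        return root_impedance(0.05, p, FLUID, WALL, period, n)

    def test_kernel_real_and_dc_consistent(self):
        spec = self._spectrum(256)
        # mean(z) * period = Z_DC
        assert np.sum(spec.kernel) * spec.dt == pytest.approx(spec.z_dc, rel=1e-10)

    def test_round_trip_recovers_spectrum(self):
        spec = self._spectrum(256)
        back = np.fft.rfft(spec.kernel) * spec.period / 256
        ref = np.array(spec.Z[:129], dtype=complex)
        ref[0] = ref[0].real
        ref[-1] = ref[-1].real
        assert np.max(np.abs(back - ref)) / np.max(np.abs(ref)) < 1e-10

    def test_constant_spectrum_is_discrete_delta(self):
        n = 64
        R = 5.0e4
        spec = ImpedanceSpectrum(
            period=0.9,
            omega=2 * np.pi * np.arange(n // 2 + 1) / 0.9,
            Z=np.full(n // 2 + 1, complex(R)),
        )
        kernel = impedance_to_kernel(spec, n)
        dt = 0.9 / n
        assert kernel[0] * dt == pytest.approx(R, rel=1e-12)
        assert np.max(np.abs(kernel[1:])) * dt < 1e-12 * R

    def test_missing_harmonics_rejected(self):
        spec = self._spectrum(64)
        with pytest.raises(ValueError, match="harmonics"):
            impedance_to_kernel(spec, 256)

    def test_spectrum_export_columns(self):
        df = self._spectrum(64).to_frame()
        assert list(df.columns) == ["harmonic_index", "omega", "Re_Z", "Im_Z"]
        assert df["Im_Z"].iloc[0] == 0.0
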