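"""1D scheme: tube law, interior conservation, characteristics, closures."""

import math

import numpy as np
import pytest

from corowave.config import MMHG, Config
from corowave.fixtures import single_vessel_tree
from corowave.geometry import CoronaryTree, VesselSegment
from corowave.solver import (
    Network,
    junction_solve,
    lax_wendroff_step,
    outlet_update,
    run_to_periodic,
    tube_law_pressure,
    wave_speed,
)


def _uniform_net(length=20.0, r=0.15, dx=0.05, p0_ref=80.0):
    cfg = Config.default()
    cfg.numerics.dx_max = dx
    net = Network(single_vessel_tree(length, r, r), cfg)
    net.set_reference_pressure(p0_ref, p0_ref)
    return net, cfg


class TestTubeLaw:
    def test_reference_state(self):
        wall = Config.default().wall
        wall.p0_ref = 75.0
        p, dpda = tube_law_pressure(0.05, 0.05, 0.12, wall)
        assert p == pytest.approx(75.0)
        assert dpda > 0

    def test_large_area_asymptote(self):
        wall = Config.default().wall
        f = (4.0 / 3.0) * float(wall.eh_over_r0(0.12))
        p, _ = tube_law_pressure(1e9 * 0.05, 0.05, 0.12, wall)
        assert p == pytest.approx(f / MMHG, rel=1e-4)

    def test_strictly_monotone(self):
        wall = Config.default().wall
        A = np.linspace(0.2, 5.0, 200) * 0.05
        p, dpda = tube_law_pressure(A, 0.05, 0.12, wall)
        assert np.all(np.diff(p) > 0)
        assert np.all(dpda > 0)

    def test_linear_variant_monotone(self):
        wall = Config.default().wall
        wall.linear_tube_law = True
        A = np.linspace(0.2, 5.0, 100) * 0.05
        p, dpda = tube_law_pressure(A, 0.05, 0.12, wall)
        assert np.all(np.diff(p) > 0)
        assert np.all(dpda > 0)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            tube_law_pressure(0.0, 0.05, 0.12, Config.default().wall)


class TestInteriorScheme:
    def test_constant_state_is_exact(self):
        net, _ = _uniform_net()
        A = net.A0.copy()
        Q = np.zeros_like(A)
        dt = 2e-5
        for _ in range(50):
            A, Q = lax_wendroff_step(net, A, Q, dt)
        assert np.array_equal(A, net.A0)
        assert np.all(Q == 0.0)

    def test_per_step_volume_conservation(self):
        net, _ = _uniform_net(dx=0.1)
        rng = np.random.default_rng(7)
        A = net.A0 * (1.0 + 0.01 * np.exp(-((net.x - 10.0) / 2.0) ** 2))
        Q = 0.5 * rng.random(net.n_nodes) * 0 + 0.3 * np.exp(-((net.x - 10.0) / 2.0) ** 2)
        dt = 2e-5
        interior = slice(1, net.n_nodes - 1)
        vol0 = np.sum(A[interior]) * net.dxn[1]
        An, Qn, F1h = lax_wendroff_step(net, A, Q, dt, return_flux=True)
        vol1 = np.sum(An[interior]) * net.dxn[1]
        influx = (F1h[0] - F1h[-1]) * dt
        assert vol1 - vol0 == pytest.approx(influx, rel=1e-10, abs=1e-14)

    def test_linear_pulse_speed(self):
        # small perturbation propagates at c = sqrt(A/rho dp/dA) within 1%
        net, cfg = _uniform_net(length=30.0, dx=0.05)
        c0 = float(wave_speed(net.A0[0], net.A0[0], net.f[0], net.rho))
        amp = 1e-4
        A = net.A0 * (1.0 + amp * np.exp(-((net.x - 8.0) / 0.8) ** 2))
        Q = np.zeros(net.n_nodes)
        dt = 0.4 * net.dxn[0] / c0
        # centroid of the forward-running half after the split
        def centroid(A):
            d = np.where(net.x > 8.0, A - net.A0, 0.0)
            return float(np.sum(net.x * d) / np.sum(d))

        n1, n2 = 120, 320
        for k in range(n2):
            if k == n1:
                x1 = centroid(A)
            A, Q = lax_wendroff_step(net, A, Q, dt)
        x2 = centroid(A)
        speed = (x2 - x1) / ((n2 - n1) * dt)
        assert speed == pytest.approx(c0, rel=0.01)

    def test_negative_area_aborts_with_location(self):
        net, _ = _uniform_net(dx=0.5)
        A = net.A0.copy()
        A[5] = 1e-9
        Q = np.zeros_like(A)
        Q[4:7] = 50.0
        with pytest.raises(FloatingPointError, match="negative area"):
            for _ in range(50):
                A, Q = lax_wendroff_step(net, A, Q, 5e-4)


def test_order_of_accuracy_on_smooth_pulse():
    """Halving dx and dt reduces the solution change ~4x (second order)."""
    fields = {}
    for dx in (0.2, 0.1, 0.05):
        net, _ = _uniform_net(length=16.0, dx=dx)
        c0 = float(wave_speed(net.A0[0], net.A0[0], net.f[0], net.rho))
        A = net.A0 * (1.0 + 0.01 * np.exp(-((net.x - 5.0) / 1.0) ** 2))
        Q = np.zeros(net.n_nodes)
        n_steps = int(round(0.003 * c0 / (0.25 * dx)))
        dt = 0.003 / n_steps
        for _ in range(n_steps):
            A, Q = lax_wendroff_step(net, A, Q, dt)
        fields[dx] = (A, net.x)
    # compare on the coarse grid nodes (shared x positions)
    A_c, x_c = fields[0.2]
    A_m, x_m = fields[0.1]
    A_f, x_f = fields[0.05]
    Am_on_c = np.interp(x_c, x_m, A_m)
    Af_on_c = np.interp(x_c, x_f, A_f)
    e_coarse = np.max(np.abs(A_c - Af_on_c))
    e_mid = np.max(np.abs(Am_on_c - Af_on_c))
    ratio = e_coarse / e_mid
    assert 3.0 < ratio < 5.5


def _y_network(r_d2=0.12, dx=0.1):
    segs = {
        "P": VesselSegment(name="P", length=4.0, r_prox=0.16, r_dist=0.16,
                           daughters=["D1", "D2"]),
        "D1": VesselSegment(name="D1", length=4.0, r_prox=0.12, r_dist=0.12, parent="P"),
        "D2": VesselSegment(name="D2", length=4.0, r_prox=r_d2, r_dist=r_d2, parent="P"),
    }
    tree = CoronaryTree(segments=segs, roots=["P"])
    cfg = Config.default()
    cfg.numerics.dx_max = dx
    net = Network(tree, cfg)
    net.set_reference_pressure(80.0, 80.0)
    return net, cfg


class TestJunction:
    def test_symmetric_split(self):
        net, cfg = _y_network()
        A = net.A0.copy()
        q0 = 2.0
        Q = np.full(net.n_nodes, 0.0)
        gp = net.grids["P"]
        Q[gp.start : gp.stop] = q0
        for d in ("D1", "D2"):
            g = net.grids[d]
            Q[g.start : g.stop] = q0 / 2
        out, res = junction_solve(net, A, Q, net.junctions[0], 1e-5,
                                  cfg.numerics.junction_tol, cfg.numerics.max_newton)
        (Ap, qp), (A1, q1), (A2, q2) = out
        assert q1 == pytest.approx(q2, rel=1e-9)
        assert qp == pytest.approx(q1 + q2, rel=1e-10)
        assert res < 1e-10

    def test_conservation_and_pressure_continuity(self):
        net, cfg = _y_network(r_d2=0.09)
        rng = np.random.default_rng(3)
        A = net.A0 * (1.0 + 0.02 * rng.random(net.n_nodes))
        Q = 1.0 + 0.5 * rng.random(net.n_nodes)
        jn = net.junctions[0]
        out, res = junction_solve(net, A, Q, jn, 2e-5,
                                  cfg.numerics.junction_tol, cfg.numerics.max_newton)
        (Ap, qp), (A1, q1), (A2, q2) = out
        assert abs(qp - q1 - q2) < 1e-10 * max(abs(qp), 1.0)
        # the three boundary areas correspond to one common pressure
        p_p = net.pressure(np.where(np.arange(net.n_nodes) == jn.p_b, Ap, A))[jn.p_b]
        p_1 = net.pressure(np.where(np.arange(net.n_nodes) == jn.d1_b, A1, A))[jn.d1_b]
        assert p_p == pytest.approx(p_1, rel=1e-12)

    def test_occluded_daughter_starves(self):
        # micro daughter receives a negligible share of the parent flow
        net, cfg = _y_network(r_d2=0.012)
        A = net.A0.copy()
        Q = np.zeros(net.n_nodes)
        gp = net.grids["P"]
        Q[gp.start : gp.stop] = 2.0
        g1 = net.grids["D1"]
        Q[g1.start : g1.stop] = 2.0
        out, _ = junction_solve(net, A, Q, net.junctions[0], 1e-5,
                                cfg.numerics.junction_tol, cfg.numerics.max_newton)
        (_, qp), (_, q1), (_, q2) = out
        assert abs(q2) < 0.02 * abs(qp)


class TestOutlet:
    def test_ohmic_limit(self):
        net, cfg = _uniform_net(dx=0.5)
        A = net.A0.copy()
        Q = np.full(net.n_nodes, 1.5)
        b = net.n_nodes - 1
        R = 2.0e4
        p_f = 30.0 * MMHG
        Ab, qb = outlet_update(net, A, Q, b, b - 1, 1e-5, R, 0.0, p_f, 1e-13, 60)
        p = float(net.pressure(np.where(np.arange(net.n_nodes) == b, Ab, A))[b])
        assert p == pytest.approx(R * qb + p_f, rel=1e-10)

    def test_no_flow_limit(self):
        # at rest with p_f equal to the resting pressure: p(L) = p_f, q = 0
        net, _ = _uniform_net(dx=0.5, p0_ref=80.0)
        A = net.A0.copy()
        Q = np.zeros(net.n_nodes)
        b = net.n_nodes - 1
        p_f = 80.0 * MMHG
        Ab, qb = outlet_update(net, A, Q, b, b - 1, 1e-5, 0.0, 0.0, p_f, 1e-13, 60)
        assert qb == pytest.approx(0.0, abs=1e-10)
        p = float(net.pressure(np.where(np.arange(net.n_nodes) == b, Ab, A))[b])
        assert p == pytest.approx(p_f, rel=1e-12)


class TestRunToPeriodic:
    def test_single_vessel_converges_quickly(self):
        cfg = Config.fast()
        cfg.numerics.n_samples = 256
        tree = single_vessel_tree(length=10.0, r_prox=0.15, r_dist=0.14)
        res = run_to_periodic(tree=tree, cfg=cfg)
        assert res.cycles <= 8
        assert res.convergence[-1] < cfg.numerics.polish_tol_mmhg
        assert res.mass_balance("V") < 1e-3

    def test_kernel_matches_reference_python_path(self):
        # identical physics through the compiled and plain-python cycle loops
        cfg = Config.fast()
        cfg.numerics.n_samples = 256
        cfg.numerics.min_nodes = 3
        cfg.numerics.dx_max = 1.0
        cfg.trifurcation.length = 0.5
        res_k = run_to_periodic(cfg=cfg)
        res_p = run_to_periodic(cfg=cfg, force_python=True)
        assert np.max(np.abs(res_k.P - res_p.P)) < 1e-8
        assert np.max(np.abs(res_k.Q - res_p.Q)) < 1e-8

    def test_baseline_flow_fraction_calibrated(self, baseline):
        run = baseline.run
        target = run.config.inlet.coronary_fraction
        assert abs(run.coronary_fraction - target) <= run.config.inlet.fraction_tol

    def test_grid_refinement_stable(self, baseline, cfg_coarse):
        import copy

        cfg = copy.deepcopy(cfg_coarse)
        cfg.numerics.dx_max = 0.1
        fine = run_to_periodic(cfg=cfg)
        p_c = baseline.run.p("LCX").max()
        p_f = fine.p("LCX").max()
        assert abs(p_c - p_f) / p_f < 0.01
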