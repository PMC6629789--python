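"""Baseline and pathological scenario runs with wave-energy summaries.

Four pathological variations of the baseline model:

* Case A - arterial stiffening: the wall-law offset k3 doubled.
* Case B - microvascular rarefaction: the structured-tree radius
  exponent xi reduced from 2.76 to 2.4 (with alpha, beta recomputed
  from xi and the asymmetry ratio, so the impedance of every vascular
  bed rises).
* Case C - myocardial feedback sweep: the feedback ratio phi of one
  terminal bed varied from 0 to 60%.
* Case D - geometry scaling: all lengths and radii scaled by
  90/95/105/110%, with peak flow, pressure and wave-intensity metrics
  reported as percent of baseline.

Every scenario is a pure function of (base config, overrides): rerunning
with the same discretization yields identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import Config
from .geometry import (
    alpha_beta_from_exponent,
    load_vessel_table,
    scale_tree,
    split_trifurcation,
)
from .solver import Network, RunResult, run_to_periodic
from .wia import (
    SixWaveTable,
    WaveDecomposition,
    decompose_cycle,
    energy_table,
    pulse_wave_velocity,
    segment_six_waves,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "run_scenario",
    "run_baseline",
    "run_case_A",
    "run_case_B",
    "run_case_C",
    "run_case_D",
    "analyze_wia",
]


@dataclass
class Scenario:
    """A named variation of the baseline configuration."""

    name: str
    overrides: Dict[str, object] = field(default_factory=dict)
    geometry_scale: float = 1.0
    scale_lcx_only: bool = False
    probe_vessels: Tuple[str, ...] = ("LCX",)

    def apply(self, cfg: Config) -> Config:
        for path, value in self.overrides.items():
            cfg = cfg.override(path, value)
        return cfg


@dataclass
class ScenarioResult:
    scenario: Scenario
    run: RunResult
    wia: Dict[str, WaveDecomposition]
    six_waves: Dict[str, SixWaveTable]
    metrics: Dict[str, float]

    @property
    def config(self) -> Config:
        return self.run.config


def analyze_wia(run: RunResult, vessel: str, station="mid") -> Tuple[WaveDecomposition, SixWaveTable]:
    """Wavefront decomposition and six-wave table at a probe station."""
    cfg = run.config
    k = run._station(vessel, station)
    c_p = pulse_wave_velocity(
        run.A[k], run.net.A0[k], run.net.r0[k], cfg.wall, cfg.fluid
    )
    dec = decompose_cycle(run.t, run.P[k], run.Q[k] / run.A[k], cfg.fluid.rho, c_p)
    table = segment_six_waves(dec, cfg.ventricle_left.t_s)
    return dec, table


def _metrics(run: RunResult, dec: WaveDecomposition, table: SixWaveTable,
             vessel: str = "LCX") -> Dict[str, float]:
    u = run.u(vessel)
    p = run.p(vessel)
    q = run.q(vessel)
    wi_net = dec.WI_net
    fdw = next((l for l in table.lobes if l.label == "d"), None)
    return {
        "u_peak": float(u.max()),
        "p_peak": float(p.max()),
        "q_peak": float(q.max()),
        "wi_peak": float(np.max(np.abs(wi_net))),
        "fdw_peak": float(fdw.peak) if fdw else 0.0,
        "coronary_fraction": run.coronary_fraction,
    }


def run_scenario(scenario: Scenario, cfg: Optional[Config] = None,
                 geometry_path=None, **run_kw) -> ScenarioResult:
    cfg = scenario.apply(cfg or Config.default())
    tree = load_vessel_table(geometry_path)
    if scenario.geometry_scale != 1.0 and not scenario.scale_lcx_only:
        tree = scale_tree(tree, scenario.geometry_scale)
        cfg = cfg.override("trifurcation.radius", cfg.trifurcation.radius * scenario.geometry_scale)
        cfg = cfg.override("trifurcation.length", cfg.trifurcation.length * scenario.geometry_scale)
    tree = split_trifurcation(tree, cfg.trifurcation)
    if scenario.geometry_scale != 1.0 and scenario.scale_lcx_only:
        tree = scale_tree(tree, scenario.geometry_scale, lcx_only=True)
    run = run_to_periodic(tree=tree, cfg=cfg, **run_kw)
    wia: Dict[str, WaveDecomposition] = {}
    tables: Dict[str, SixWaveTable] = {}
    for v in scenario.probe_vessels:
        dec, tab = analyze_wia(run, v)
        wia[v] = dec
        tables[v] = tab
    probe = scenario.probe_vessels[0]
    metrics = _metrics(run, wia[probe], tables[probe], probe)
    return ScenarioResult(scenario=scenario, run=run, wia=wia,
                          six_waves=tables, metrics=metrics)


def run_baseline(cfg: Optional[Config] = None,
                 probe_vessels: Tuple[str, ...] = ("LCX",), **kw) -> ScenarioResult:
    return run_scenario(Scenario(name="baseline", probe_vessels=probe_vessels), cfg, **kw)


def run_case_A(cfg: Optional[Config] = None, **kw) -> ScenarioResult:
    """Stiffening: k3 increased by 100% everywhere."""
    base = cfg or Config.default()
    sc = Scenario(name="case_A", overrides={"wall.k3": 2.0 * base.wall.k3})
    return run_scenario(sc, base, **kw)


def run_case_B(cfg: Optional[Config] = None, xi: float = 2.4, **kw) -> ScenarioResult:
    """Rarefaction: radius exponent reduced (affects bed impedance only)."""
    base = cfg or Config.default()
    alpha, beta = alpha_beta_from_exponent(xi, base.tree.gamma)
    sc = Scenario(
        name="case_B",
        overrides={"tree.xi": xi, "tree.alpha": alpha, "tree.beta": beta},
    )
    return run_scenario(sc, base, **kw)


def run_case_C(cfg: Optional[Config] = None,
               phi_values: Sequence[float] = (0.0, 0.22, 0.33, 0.6),
               terminal: str = "LAD1", **kw) -> Dict[float, ScenarioResult]:
    """Feedback sweep: phi of one terminal bed varied."""
    base = cfg or Config.default()
    out: Dict[float, ScenarioResult] = {}
    for phi in phi_values:
        sc = Scenario(
            name=f"case_C_phi{phi:g}",
            overrides={"feedback.phi_overrides": {terminal: float(phi)}},
            probe_vessels=("LCX", terminal),
        )
        out[float(phi)] = run_scenario(sc, base, **kw)
    return out


def run_case_D(cfg: Optional[Config] = None,
               scales: Sequence[float] = (0.90, 0.95, 1.05, 1.10),
               baseline: Optional[ScenarioResult] = None,
               lcx_only: bool = False, **kw):
    """Geometry scaling; returns (per-scale results, percent-of-baseline table)."""
    import pandas as pd

    base = cfg or Config.default()
    if baseline is None:
        baseline = run_baseline(base, **kw)
    results: Dict[float, ScenarioResult] = {}
    rows = []
    for s in scales:
        sc = Scenario(name=f"case_D_{int(round(100 * s))}",
                      geometry_scale=float(s), scale_lcx_only=lcx_only)
        res = run_scenario(sc, base, **kw)
        results[float(s)] = res
        rows.append(
            {
                "size_percent": round(100.0 * s, 9),
                "flow_peak_percent": 100.0 * res.metrics["q_peak"] / baseline.metrics["q_peak"],
                "pressure_peak_percent": 100.0 * res.metrics["p_peak"] / baseline.metrics["p_peak"],
                "wi_peak_percent": 100.0 * res.metrics["wi_peak"] / baseline.metrics["wi_peak"],
                "fdw_peak_percent": (
                    100.0 * res.metrics["fdw_peak"] / baseline.metrics["fdw_peak"]
                    if baseline.metrics["fdw_peak"] > 0
                    else float("nan")
                ),
            }
        )
    table = pd.DataFrame(rows).set_index("size_percent")
    return results, table, baseline
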