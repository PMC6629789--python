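"""Shared fixtures: the heavy periodic runs are computed once per session."""

from __future__ import annotations

import pytest

from corowave.config import Config
from corowave.scenarios import (
    run_baseline,
    run_case_A,
    run_case_B,
    run_case_C,
    run_case_D,
)


@pytest.fixture(scope="session")
def cfg_coarse() -> Config:
    return Config.coarse()


@pytest.fixture(scope="session")
def baseline(cfg_coarse):
    """Converged baseline run with probes in the main vessels."""
    return run_baseline(cfg_coarse, probe_vessels=("LCX", "LMCA", "RCA", "LAD"))


@pytest.fixture(scope="session")
def case_a(cfg_coarse):
    return run_case_A(cfg_coarse)


@pytest.fixture(scope="session")
def case_b(cfg_coarse):
    return run_case_B(cfg_coarse)


@pytest.fixture(scope="session")
def case_c(cfg_coarse):
    return run_case_C(cfg_coarse, phi_values=(0.0, 0.22, 0.6))


@pytest.fixture(scope="session")
def case_d(cfg_coarse, baseline):
    results, table, _ = run_case_D(cfg_coarse, baseline=baseline)
    return results, table
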