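"""Model configuration: physical constants, parameter groups, YAML I/O.

All internal quantities are CGS (g, cm, s).  Pressures cross the API in
mmHg and are converted at the boundary (1 mmHg = 1333.22 g cm^-1 s^-2),
because the wall-law and structured-tree parameters are tabulated in CGS
while physiological pressures are universally quoted in mmHg.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: 1 mmHg in CGS pressure units (g cm^-1 s^-2 == dyn cm^-2).
MMHG = 1333.22

#: 1 litre/minute in CGS flow units (cm^3 s^-1).
LPM = 1000.0 / 60.0


def mmhg_to_cgs(p: float) -> float:
    return p * MMHG


def cgs_to_mmhg(p: float) -> float:
    return p / MMHG


@dataclass
class FluidParams:
    """Blood rheology (Newtonian, incompressible)."""

    rho: float = 1.055      # g cm^-3
    mu: float = 0.0047      # g cm^-1 s^-1

    @property
    def nu(self) -> float:
        """Kinematic viscosity, cm^2 s^-1."""
        return self.mu / self.rho


@dataclass
class WallLaw:
    """Elastic wall stiffness Eh/r0 = k1 exp(k2 r0) + k3.

    Units as tabulated: k1, k3 in g s^-2 cm^-1 (so that Eh/r0 is a
    pressure-like modulus), k2 in cm^-1.  ``p0_ref`` is the reference
    pressure of the tube law in mmHg; the solver overwrites it per tree
    side with the time-averaged ventricular pressure.
    """

    k1: float = 2.0e7
    k2: float = -22.5
    k3: float = 8.65e5
    p0_ref: float = 0.0     # mmHg; set at run time per tree side
    linear_tube_law: bool = False   # sensitivity switch: use 1 - A/A0

    def eh_over_r0(self, r0):
        import numpy as np

        return self.k1 * np.exp(self.k2 * r0) + self.k3


@dataclass
class StructuredTreeParams:
    """Self-similar binary vascular-bed tree.

    Daughter radii are ``alpha * r`` and ``beta * r``; branching stops
    when a daughter would fall below ``r_min``; each vessel's length is
    ``l_rr`` times its radius.  ``xi`` is the radius exponent of
    r_p^xi = r_d1^xi + r_d2^xi; ``gamma`` (asymmetry) and ``eta`` (area
    ratio) are reported alongside but are consequences of alpha/beta/xi.
    """

    alpha: float = 0.9
    beta: float = 0.6
    xi: float = 2.76
    gamma: float = 0.41
    eta: float = 1.16
    r_min: float = 1.0e-3   # cm (10 um)
    l_rr: float = 25.0
    z_terminal: float = 0.0  # distal load of the smallest vessels, g cm^-4 s^-1

    def validate(self) -> None:
        if not (0.0 < self.beta < self.alpha < 1.0):
            raise ValueError(
                f"require 0 < beta < alpha < 1, got alpha={self.alpha}, beta={self.beta}"
            )
        if not (2.33 <= self.xi <= 3.0):
            raise ValueError(f"radius exponent xi={self.xi} outside [2.33, 3]")
        if self.r_min <= 0:
            raise ValueError("r_min must be positive")


@dataclass
class VentricleParams:
    """Time-varying elastance ventricle (pressures in mmHg, volumes in ml)."""

    p0: float = 50.0        # peak isovolumetric pressure coefficient, mmHg
    Es: float = 1.375       # systolic elastance, mmHg ml^-1
    Ed: float = 0.1         # diastolic elastance, mmHg ml^-1
    V0: float = 11.29       # unstressed volume, ml
    Rv: float = 0.08        # myocardial resistance, mmHg s ml^-1
    t_s: float = 0.4        # end of systole, s
    t_c: float = 0.9        # cardiac period, s
    side: str = "left"
    sigma_half: bool = False  # if True, halve the activation (peak 1 not 2)

    def validate(self) -> None:
        if not (0.0 < self.t_s < self.t_c):
            raise ValueError(f"require 0 < t_s < t_c, got t_s={self.t_s}, t_c={self.t_c}")
        if not (self.Es > self.Ed > 0.0):
            raise ValueError(f"require Es > Ed > 0, got Es={self.Es}, Ed={self.Ed}")


RIGHT_VENTRICLE_DEFAULTS = dict(
    p0=24.0, Es=0.3288, Ed=0.03, V0=3.33, Rv=0.0175, side="right"
)


@dataclass
class VolumeModelParams:
    """Prescribed ventricular volume waveform V(t).

    The elastance pressure law needs only (V - V0) and dV/dt, so V(t) is a
    smooth prescribed stroke profile: a C1 cosine ejection ramp from V_ed
    down by SV over [t_ej0, t_ej1], a hold, then a C1 refill in diastole.
    Defaults give a left peak ventricular pressure of ~120 mmHg and a
    cardiac output of ~4.6 L/min at t_c = 0.9 s.
    """

    V_ed: float = 85.0      # end-diastolic volume, ml
    SV: float = 65.0        # stroke volume, ml
    t_ej0: float = 0.02     # ejection onset, s
    t_ej1: float = 0.22     # ejection end, s
    t_fill0: float = 0.45   # refill onset, s
    t_fill1: float = 0.88   # refill end, s


@dataclass
class FeedbackParams:
    """Myocardial feedback pressure p_f = phi * p_v + p_s at terminal beds."""

    p_s: float = 20.0       # coronary bed pressure, mmHg
    phi_left_ventricle: float = 0.33
    phi_right_ventricle: float = 0.25
    phi_septum: float = 0.22
    phi_overrides: dict = field(default_factory=dict)  # terminal name -> phi


@dataclass
class InletParams:
    """Aortic-root driving condition.

    The lumped systemic model is an elastance ventricle ejecting through
    a diode valve into a 3-element windkessel, giving the aortic-root
    pressure.  In the default ``flow`` mode the coronary inflow of each
    root is estimated from that pressure and the time-varying Thevenin
    feedback of its vascular beds, then scaled so total mean coronary
    inflow equals ``coronary_fraction`` of cardiac output.  In
    ``pressure`` mode the aortic pressure itself (times a calibrated
    scale factor) is imposed at the roots instead.
    """

    mode: str = "flow"              # "flow" | "pressure"
    coronary_fraction: float = 0.045
    fraction_tol: float = 0.001
    R_char: float = 0.06            # windkessel characteristic resistance, mmHg s ml^-1
    R_per: float = 1.05             # peripheral resistance, mmHg s ml^-1
    C_art: float = 1.4              # arterial compliance, ml mmHg^-1
    p_venous: float = 5.0           # venous pressure, mmHg
    scale: float = 1.0              # inlet scale factor (calibrated)


@dataclass
class NumericsParams:
    """Discretization and convergence controls."""

    dx_max: float = 0.1     # cm; target grid spacing per vessel
    min_nodes: int = 8      # minimum grid nodes per vessel
    cfl: float = 0.5
    n_samples: int = 4096   # samples per period for impedance kernel / outputs
    conv_tol_mmhg: float = 0.5   # cycle-to-cycle Linf pressure tolerance
    polish_tol_mmhg: float = 0.05  # extra periodicity polish of the final cycle
    max_cycles: int = 20
    junction_tol: float = 1.0e-11
    max_newton: int = 60


@dataclass
class TrifurcationParams:
    """Intermediate segment replacing the LMCA trifurcation."""

    radius: float = 0.185   # cm (printed value; Eq-1 recomputation differs)
    length: float = 0.25    # cm
    name: str = "D2"


@dataclass
class Config:
    fluid: FluidParams = field(default_factory=FluidParams)
    wall: WallLaw = field(default_factory=WallLaw)
    tree: StructuredTreeParams = field(default_factory=StructuredTreeParams)
    ventricle_left: VentricleParams = field(default_factory=VentricleParams)
    ventricle_right: VentricleParams = field(
        default_factory=lambda: VentricleParams(**RIGHT_VENTRICLE_DEFAULTS)
    )
    volume: VolumeModelParams = field(default_factory=VolumeModelParams)
    feedback: FeedbackParams = field(default_factory=FeedbackParams)
    inlet: InletParams = field(default_factory=InletParams)
    numerics: NumericsParams = field(default_factory=NumericsParams)
    trifurcation: TrifurcationParams = field(default_factory=TrifurcationParams)

    # -- presets ---------------------------------------------------------
    @classmethod
    def default(cls) -> "Config":
        return cls()

    @classmethod
    def coarse(cls) -> "Config":
        """Coarse-grid preset (dx 0.2 cm, 1024 samples per period)."""
        cfg = cls()
        cfg.numerics.dx_max = 0.2
        cfg.numerics.n_samples = 1024
        cfg.numerics.min_nodes = 4
        return cfg

    @classmethod
    def fast(cls) -> "Config":
        """Fastest preset for smoke tests (dx 0.4 cm, 512 samples)."""
        cfg = cls()
        cfg.numerics.dx_max = 0.4
        cfg.numerics.n_samples = 512
        cfg.numerics.min_nodes = 4
        return cfg

    # -- overrides -------------------------------------------------------
    def override(self, path: str, value) -> "Config":
        """Return a deep copy with ``section.field`` set to ``value``."""
        import copy

        cfg = copy.deepcopy(self)
        parts = path.split(".")
        obj = cfg
        for part in parts[:-1]:
            if not hasattr(obj, part):
                raise KeyError(f"unknown config path {path!r}")
            obj = getattr(obj, part)
        leaf = parts[-1]
        if isinstance(obj, dict):
            obj[leaf] = value
        else:
            if not hasattr(obj, leaf):
                raise KeyError(f"unknown config path {path!r}")
            setattr(obj, leaf, value)
        return cfg

    # -- YAML ------------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        cfg = cls()
        for section, payload in d.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            if not isinstance(payload, dict):
                raise TypeError(f"config section {section!r} must be a mapping")
            for key, value in payload.items():
                if not hasattr(target, key):
                    raise KeyError(f"unknown config key {section}.{key}")
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, text_or_stream) -> "Config":
        if isinstance(text_or_stream, str):
            text_or_stream = io.StringIO(text_or_stream)
        data = yaml.safe_load(text_or_stream) or {}
        return cls.from_dict(data)
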