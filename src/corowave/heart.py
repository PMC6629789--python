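"""Ventricular pressures, myocardial feedback pressure, and the inlet drive.

Ventricular pressure follows a time-varying elastance law: during
systole p_v = p0 sigma(t) + (Ed + Es sigma(t)) (V - V0) + Rv dV/dt with
activation sigma(t) = 1 - cos(2 pi t / t_s); during diastole
p_v = Ed (V - V0).  The ventricular volume V(t) is a smooth prescribed
stroke profile (the elastance law needs only V - V0 and dV/dt).

The myocardial squeeze on each terminal vascular bed enters as a
feedback pressure p_f = phi p_v + p_s added to the distal boundary
condition, with phi set by the bed's supply location (left ventricle,
right ventricle or septum).

The aortic-root drive comes from a minimal lumped systemic model: the
ejection flow max(0, -dV/dt) passes a diode valve into a 3-element
windkessel, whose periodic solution is obtained directly in the
frequency domain.  An inlet scale factor multiplying this pressure is
later calibrated (by the solver) so that total mean coronary inflow is a
configured fraction of cardiac output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    Config,
    FeedbackParams,
    InletParams,
    VentricleParams,
    VolumeModelParams,
)

__all__ = [
    "activation_sigma",
    "VolumeModel",
    "ventricular_pressure",
    "feedback_phi",
    "feedback_pressure",
    "inlet_waveform",
    "HeartDrive",
]


def activation_sigma(t, t_s: float, t_c: float, half: bool = False):
    """Activation sigma(t) = 1 - cos(2 pi t / t_s) in systole, 0 in diastole.

    Periodic with period t_c; continuous everywhere (sigma(0) =
    sigma(t_s) = 0).  Peaks at 2 at mid-systole as printed; ``half``
    applies the conventional 1/2 factor (peak 1) for sensitivity runs.
    """
    t = np.mod(np.asarray(t, dtype=float), t_c)
    sig = np.where(t < t_s, 1.0 - np.cos(2.0 * np.pi * t / t_s), 0.0)
    if half:
        sig = 0.5 * sig
    return sig


def _smoothstep(t, t0, t1):
    """C1 cosine ramp from 0 at t0 to 1 at t1 (clamped outside)."""
    x = np.clip((np.asarray(t, dtype=float) - t0) / (t1 - t0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _smoothstep_dot(t, t0, t1):
    t = np.asarray(t, dtype=float)
    x = (t - t0) / (t1 - t0)
    inside = (x > 0.0) & (x < 1.0)
    return np.where(inside, 0.5 * np.pi / (t1 - t0) * np.sin(np.pi * np.clip(x, 0, 1)), 0.0)


@dataclass
class VolumeModel:
    """Prescribed periodic ventricular volume V(t) and its rate dV/dt.

    V drops from V_ed by the stroke volume over the C1 ejection ramp
    [t_ej0, t_ej1], holds, then refills smoothly over [t_fill0, t_fill1].
    """

    params: VolumeModelParams
    t_c: float

    def ejection_fraction_profile(self, t):
        p = self.params
        t = np.mod(np.asarray(t, dtype=float), self.t_c)
        up = _smoothstep(t, p.t_ej0, p.t_ej1)
        down = _smoothstep(t, p.t_fill0, p.t_fill1)
        return up - down

    def volume(self, t):
        return self.params.V_ed - self.params.SV * self.ejection_fraction_profile(t)

    def dvolume_dt(self, t):
        p = self.params
        t = np.mod(np.asarray(t, dtype=float), self.t_c)
        return -p.SV * (_smoothstep_dot(t, p.t_ej0, p.t_ej1) - _smoothstep_dot(t, p.t_fill0, p.t_fill1))

    @property
    def cardiac_output(self) -> float:
        """Mean systemic output SV / t_c, ml s^-1."""
        return self.params.SV / self.t_c


def ventricular_pressure(t, vp: VentricleParams, vol: VolumeModel):
    """Elastance-model ventricular pressure in mmHg (vectorized over t)."""
    t = np.mod(np.asarray(t, dtype=float), vp.t_c)
    sig = activation_sigma(t, vp.t_s, vp.t_c, half=vp.sigma_half)
    v = vol.volume(t)
    dv = vol.dvolume_dt(t)
    systole = t < vp.t_s
    p_sys = vp.p0 * sig + (vp.Ed + vp.Es * sig) * (v - vp.V0) + vp.Rv * dv
    p_dia = vp.Ed * (v - vp.V0)
    return np.where(systole, p_sys, p_dia)


def feedback_phi(terminal: str, fp: FeedbackParams, supply_location: str) -> float:
    """Ventricular-pressure feedback ratio phi for one terminal vessel."""
    if terminal in fp.phi_overrides:
        return float(fp.phi_overrides[terminal])
    table = {
        "left_ventricle": fp.phi_left_ventricle,
        "right_ventricle": fp.phi_right_ventricle,
        "septum": fp.phi_septum,
    }
    if supply_location not in table:
        raise KeyError(
            f"terminal {terminal!r}: unknown supply location {supply_location!r}"
        )
    return float(table[supply_location])


def feedback_pressure(t, terminal: str, fp: FeedbackParams, supply_location: str,
                      pv_left, pv_right):
    """Feedback pressure p_f = phi p_v + p_s (mmHg) at one terminal bed.

    The driving ventricular pressure is the right ventricle's for beds in
    the right ventricular wall, otherwise the left ventricle's (septal
    beds use the left pressure with the septal phi).
    """
    phi = feedback_phi(terminal, fp, supply_location)
    p_v = pv_right if supply_location == "right_ventricle" else pv_left
    return phi * np.asarray(p_v) + fp.p_s


@dataclass
class HeartDrive:
    """Precomputed periodic waveforms of one cardiac cycle (n uniform samples)."""

    t: np.ndarray            # sample times, s
    p_aorta: np.ndarray      # aortic-root pressure, mmHg (unscaled)
    pv_left: np.ndarray      # left ventricular pressure, mmHg
    pv_right: np.ndarray     # right ventricular pressure, mmHg
    cardiac_output: float    # ml s^-1
    target_coronary_flow: float  # ml s^-1

    @property
    def p0_ref_left(self) -> float:
        return float(np.mean(self.pv_left))

    @property
    def p0_ref_right(self) -> float:
        return float(np.mean(self.pv_right))


def inlet_waveform(cfg: Config, n_samples: int = 1024) -> HeartDrive:
    """Aortic-root pressure and ventricular waveforms over one period.

    The ejection flow q_a(t) = max(0, -dV/dt) (diode valve: never
    negative) drives a 3-element windkessel R_char -- (C_art || R_per)
    referenced to venous pressure; the periodic windkessel solution is
    computed in the frequency domain.  Also reports the cardiac output
    and the target mean coronary inflow (coronary_fraction x CO).
    """
    t_c = cfg.ventricle_left.t_c
    vol = VolumeModel(cfg.volume, t_c)
    t = np.arange(n_samples) * (t_c / n_samples)
    q_a = np.maximum(0.0, -vol.dvolume_dt(t))          # ml s^-1
    inlet = cfg.inlet

    # periodic windkessel solve: C dp_c/dt = q_a - (p_c - p_ven)/R_per
    qf = np.fft.rfft(q_a)
    omega = 2.0 * np.pi * np.fft.rfftfreq(n_samples, d=t_c / n_samples)
    h = inlet.R_per / (1.0 + 1j * omega * inlet.R_per * inlet.C_art)
    pc = np.fft.irfft(qf * h, n=n_samples) + inlet.p_venous
    p_aorta = pc + inlet.R_char * q_a

    pv_left = ventricular_pressure(t, cfg.ventricle_left, vol)
    pv_right = ventricular_pressure(t, cfg.ventricle_right, vol)
    co = vol.cardiac_output
    return HeartDrive(
        t=t,
        p_aorta=p_aorta,
        pv_left=np.asarray(pv_left),
        pv_right=np.asarray(pv_right),
        cardiac_output=co,
        target_coronary_flow=inlet.coronary_fraction * co,
    )
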