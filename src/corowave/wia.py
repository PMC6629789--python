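"""Wave-intensity analysis of simulated pressure/velocity waveforms.

Forward/backward wavefronts are separated with the water-hammer
relations applied samplewise with the local (time-varying) pulse wave
velocity c_p = sqrt(A/rho dp/dA):

    dp_i^+- = (dp_i +- rho c_p,i du_i) / 2,
    du_i^+- = (du_i +- dp_i / (rho c_p,i)) / 2,

and the wave intensity is WI_i^+- = (dp_i^+- / dt)(du_i^+- / dt), so
forward intensity is non-negative and backward non-positive pointwise.

Over one coronary beat the intensity profile decomposes into six
characteristic lobes: (a) an early-systolic backward compression wave
from myocardial contraction squeezing the beds, (b) the systolic
forward compression wave from ventricular ejection, (c) a late-systolic
backward compression wave from distal reflection, (d) a proto-diastolic
forward decompression wave as the myocardium relaxes, (e) the dominant
backward decompression wave from bed decompression, and (f) a late
forward compression wave at valve closure.  ``segment_six_waves``
detects intensity lobes by thresholded zero-crossings, classifies each
by direction and compression/decompression, and matches the
chronological sequence a-f, reporting each lobe's share of cumulative
|WI| energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import MMHG, FluidParams, WallLaw

__all__ = [
    "pulse_wave_velocity",
    "decompose",
    "WaveDecomposition",
    "WaveLobe",
    "SixWaveTable",
    "segment_six_waves",
    "energy_table",
    "REFERENCE_ENERGY_COLUMNS",
]

#: Published in-vivo cumulative proportional wave-energy fractions (%),
#: shipped as static comparison metadata for report tables.
REFERENCE_ENERGY_COLUMNS: Dict[str, Dict[str, float]] = {
    "invasive human LAD (Davies)": {"a": 1.9, "b": 22.3, "c": 20.5, "d": 18.9, "e": 30.0, "f": 6.1},
    "invasive human (Lee)": {"a": 5.1, "b": 27.4, "c": 2.8, "d": 13.4, "e": 37.3, "f": 14.1},
}

WAVE_TYPES = {"a": "BCW", "b": "FCW", "c": "BCW", "d": "FDW", "e": "BDW", "f": "FCW"}


def pulse_wave_velocity(A, A0, r0, wall: WallLaw, fluid: FluidParams):
    """Local pulse wave velocity c_p = sqrt(A/rho dp/dA), cm s^-1.

    Evaluated on the simulated area series A(t) at a probe station, so
    c_p is time-varying.  For the adopted tube law c_p decreases slowly
    with distension (c_p ~ A^{-1/4}).
    """
    A = np.asarray(A, dtype=float)
    f = (4.0 / 3.0) * float(wall.eh_over_r0(r0))
    if wall.linear_tube_law:
        return np.sqrt(f * A0 / (fluid.rho * A))
    return np.sqrt(0.5 * f / fluid.rho) * (A0 / A) ** 0.25


@dataclass
class WaveDecomposition:
    """Samplewise forward/backward split of one cycle.

    Increments are periodic first differences (sample i holds the change
    from t_i to t_{i+1}, wrapping at the cycle end), so the forward and
    backward parts reconstruct the totals exactly.  Pressure increments
    in mmHg; wave intensity in CGS (dyn cm^-2 s^-1 * cm s^-2).
    """

    t: np.ndarray
    dt: float
    dp: np.ndarray          # mmHg
    du: np.ndarray          # cm s^-1
    dp_plus: np.ndarray
    dp_minus: np.ndarray
    du_plus: np.ndarray
    du_minus: np.ndarray
    c_p: np.ndarray         # cm s^-1
    WI_plus: np.ndarray
    WI_minus: np.ndarray

    @property
    def WI_net(self) -> np.ndarray:
        return self.WI_plus + self.WI_minus

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "dp_plus": self.dp_plus,
                "dp_minus": self.dp_minus,
                "du_plus": self.du_plus,
                "du_minus": self.du_minus,
                "WI_plus": self.WI_plus,
                "WI_minus": self.WI_minus,
                "WI_net": self.WI_net,
            }
        )


def decompose(p, u, rho: float, c_p) -> WaveDecomposition:
    """Split pressure (mmHg) and velocity (cm/s) series into wavefronts.

    Series must be uniformly sampled over exactly one period; the local
    pulse wave velocity series ``c_p`` may be scalar or samplewise.
    """
    p = np.asarray(p, dtype=float)
    u = np.asarray(u, dtype=float)
    if p.shape != u.shape or p.ndim != 1:
        raise ValueError("p and u must be 1-D series of equal length")
    n = len(p)
    c_p = np.broadcast_to(np.asarray(c_p, dtype=float), p.shape)
    dp_cgs = (np.roll(p, -1) - p) * MMHG
    du = np.roll(u, -1) - u
    rc = rho * c_p
    dp_pl = 0.5 * (dp_cgs + rc * du)
    dp_mi = 0.5 * (dp_cgs - rc * du)
    du_pl = 0.5 * (du + dp_cgs / rc)
    du_mi = 0.5 * (du - dp_cgs / rc)
    # dt is recovered later from the caller's time base; store index time
    t = np.arange(n, dtype=float)
    dt = 1.0
    wi_pl = dp_pl * du_pl
    wi_mi = dp_mi * du_mi
    return WaveDecomposition(
        t=t,
        dt=dt,
        dp=dp_cgs / MMHG,
        du=du,
        dp_plus=dp_pl / MMHG,
        dp_minus=dp_mi / MMHG,
        du_plus=du_pl,
        du_minus=du_mi,
        c_p=np.array(c_p),
        WI_plus=wi_pl,
        WI_minus=wi_mi,
    )


def decompose_cycle(t, p, u, rho, c_p) -> WaveDecomposition:
    """:func:`decompose` with a real time base (t uniform over one cycle)."""
    dec = decompose(p, u, rho, c_p)
    t = np.asarray(t, dtype=float)
    dt = float(t[1] - t[0])
    dec.t = t
    dec.dt = dt
    dec.WI_plus = dec.WI_plus / dt**2
    dec.WI_minus = dec.WI_minus / dt**2
    return dec


@dataclass
class WaveLobe:
    label: Optional[str]
    wave_type: str          # FCW | FDW | BCW | BDW
    i_start: int
    i_end: int              # inclusive
    t_start: float
    t_end: float
    energy: float           # integral of |WI| dt over the lobe
    peak: float             # max |WI| within the lobe


@dataclass
class SixWaveTable:
    """Energy shares of the six labeled coronary waves."""

    lobes: List[WaveLobe]
    percents: Dict[str, float]
    energies: Dict[str, float]
    total_energy: float
    unlabeled_energy: float
    complete: bool
    warning: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lbl in "abcdef":
            lobe = next((l for l in self.lobes if l.label == lbl), None)
            rows.append(
                {
                    "wave": lbl,
                    "type": WAVE_TYPES[lbl],
                    "t_start": lobe.t_start if lobe else np.nan,
                    "t_end": lobe.t_end if lobe else np.nan,
                    "energy": self.energies.get(lbl, np.nan),
                    "percent": self.percents.get(lbl, np.nan),
                }
            )
        return pd.DataFrame(rows)


def _find_lobes(series, dp_dir, t, dt, thr) -> List[WaveLobe]:
    """Contiguous |WI| > thr runs of one directional intensity series."""
    mask = np.abs(series) > thr
    lobes: List[WaveLobe] = []
    n = len(series)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        seg = slice(i, j + 1)
        net_dp = float(np.sum(dp_dir[seg]))
        forward = series[seg].sum() >= 0.0
        if forward:
            wtype = "FCW" if net_dp >= 0 else "FDW"
        else:
            wtype = "BCW" if net_dp >= 0 else "BDW"
        lobes.append(
            WaveLobe(
                label=None,
                wave_type=wtype,
                i_start=i,
                i_end=j,
                t_start=float(t[i]),
                t_end=float(t[j]),
                energy=float(np.sum(np.abs(series[seg])) * dt),
                peak=float(np.max(np.abs(series[seg]))),
            )
        )
        i = j + 1
    return lobes


def segment_six_waves(dec: WaveDecomposition, t_s: float,
                      threshold_frac: float = 0.01) -> SixWaveTable:
    """Label the six coronary wave lobes and their energy fractions.

    Lobes are contiguous excursions of WI+ or WI- beyond
    ``threshold_frac`` of the global |WI| peak; each is classified by
    direction and by the sign of its net directional pressure increment,
    then the chronological lobe sequence is matched against the expected
    pattern a:BCW, b:FCW, c:BCW, d:FDW, e:BDW, f:FCW (maximizing matched
    energy over order-preserving assignments).  Percentages are shares
    of the total energy of the six labeled lobes.
    """
    peak = max(float(np.max(np.abs(dec.WI_plus))), float(np.max(np.abs(dec.WI_minus))))
    if peak == 0.0:
        return SixWaveTable([], {}, {}, 0.0, 0.0, False, "flat wave intensity")
    thr = threshold_frac * peak
    lobes = _find_lobes(dec.WI_plus, dec.dp_plus, dec.t, dec.dt, thr)
    lobes += _find_lobes(dec.WI_minus, dec.dp_minus, dec.t, dec.dt, thr)
    lobes.sort(key=lambda l: (l.i_start, l.i_end))

    expected = [(lbl, WAVE_TYPES[lbl]) for lbl in "abcdef"]
    # order-preserving assignment maximizing matched energy (DP over
    # expected slots x lobes)
    n_l = len(lobes)
    NEG = -1.0
    best = np.full((7, n_l + 1), NEG)
    best[0, :] = 0.0
    choice = np.zeros((7, n_l + 1), dtype=int)  # 0 = skip lobe, 1 = take
    for s in range(1, 7):
        lbl, wtype = expected[s - 1]
        for k in range(n_l + 1):
            # leave this expected slot unmatched
            if best[s - 1, k] > best[s, k]:
                best[s, k] = best[s - 1, k]
                choice[s, k] = 2
            # skip this lobe
            if k > 0 and best[s, k - 1] > best[s, k]:
                best[s, k] = best[s, k - 1]
                choice[s, k] = 0
            # assign this lobe to this slot
            if k > 0 and lobes[k - 1].wave_type == wtype and best[s - 1, k - 1] >= 0.0:
                cand = best[s - 1, k - 1] + lobes[k - 1].energy
                if cand > best[s, k]:
                    best[s, k] = cand
                    choice[s, k] = 1
    assigned: Dict[str, WaveLobe] = {}
    s, k = 6, n_l
    while s > 0:
        if choice[s, k] == 2:
            s -= 1
        elif choice[s, k] == 1:
            assigned[expected[s - 1][0]] = lobes[k - 1]
            s -= 1
            k -= 1
        else:
            if k == 0:
                s -= 1
            else:
                k -= 1

    complete = len(assigned) == 6
    warning = None
    if not complete:
        warning = (
            f"only {len(assigned)} of six expected wave lobes found "
            f"({len(lobes)} candidate lobes)"
        )
    for lbl, lobe in assigned.items():
        lobe.label = lbl
    energies = {lbl: lobe.energy for lbl, lobe in assigned.items()}
    total = sum(energies.values())
    percents = {lbl: 100.0 * e / total for lbl, e in energies.items()} if total > 0 else {}
    all_energy = sum(l.energy for l in lobes)
    return SixWaveTable(
        lobes=lobes,
        percents=percents,
        energies=energies,
        total_energy=total,
        unlabeled_energy=all_energy - total,
        complete=complete,
        warning=warning,
    )


def energy_table(tables: Dict[str, SixWaveTable],
                 include_reference: bool = True) -> pd.DataFrame:
    """Side-by-side percent-energy report for several scenarios.

    Columns: one per scenario, plus the published in-vivo reference
    columns as static comparison metadata.
    """
    if not tables:
        raise ValueError("need at least one six-wave table")
    data = {}
    if include_reference:
        for name, ref in REFERENCE_ENERGY_COLUMNS.items():
            data[name] = [ref[lbl] for lbl in "abcdef"]
    for name, tab in tables.items():
        data[name] = [tab.percents.get(lbl, np.nan) for lbl in "abcdef"]
    idx = [f"({lbl}) {WAVE_TYPES[lbl]}" for lbl in "abcdef"]
    return pd.DataFrame(data, index=idx)
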