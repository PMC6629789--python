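"""Large-artery network and structured-tree branching geometry.

The large coronary arteries form two binary trees rooted at the LMCA and
RCA.  Each segment is a tapered tube described by its length and
proximal/distal radii.  The single anatomical trifurcation at the end of
the LMCA (LAD, LCX, DIAG) is replaced by two adjacent bifurcations via a
short intermediate segment, so that every junction the solver sees is a
bifurcation.

Each *terminal* large artery feeds a vascular bed modelled as a
self-similar structured tree: daughters of a vessel of radius r have
radii alpha*r and beta*r (0 < beta < alpha < 1), lengths l_rr times
their radius, and branching stops when a daughter would fall below the
minimum radius r_min.  Because the tree is self-similar, a vessel is
fully determined by its number of alpha-steps and beta-steps from the
root, so the whole bed is indexed by the (i, j) radius lattice rather
than enumerated vessel by vessel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .config import StructuredTreeParams, TrifurcationParams

__all__ = [
    "VesselSegment",
    "CoronaryTree",
    "load_vessel_table",
    "packaged_table_path",
    "split_trifurcation",
    "check_branching_relations",
    "structured_tree_radii",
    "SUPPLY_LOCATIONS",
]

#: Terminal-vessel supply locations within the myocardium (feedback ratios
#: attach per location: left ventricle 33%, right ventricle 25%, septum 22%).
SUPPLY_LOCATIONS: Dict[str, str] = {
    "PDA": "left_ventricle",
    "LAD3": "left_ventricle",
    "LAD4": "left_ventricle",
    "DIAG": "left_ventricle",
    "MARG1": "left_ventricle",
    "MARG2": "left_ventricle",
    "MARG3": "left_ventricle",
    "PLA": "right_ventricle",
    "LAD1": "septum",
    "LCX3": "septum",
}


@dataclass
class VesselSegment:
    """One tapered large artery.

    Lengths and radii in cm.  ``daughters`` has 0 (terminal) or 2 entries
    after trifurcation splitting.
    """

    name: str
    length: float
    r_prox: float
    r_dist: float
    parent: Optional[str] = None
    daughters: List[str] = field(default_factory=list)
    supply_location: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: non-positive length {self.length}")
        if self.r_dist <= 0 or self.r_prox <= 0:
            raise ValueError(f"{self.name}: non-positive radius")
        if self.r_dist > self.r_prox + 1e-12:
            raise ValueError(
                f"{self.name}: distal radius {self.r_dist} exceeds proximal {self.r_prox}"
            )

    @property
    def terminal(self) -> bool:
        return not self.daughters

    def r0(self, x: float) -> float:
        """Reference radius at centreline position x (linear taper)."""
        return self.r_prox + (self.r_dist - self.r_prox) * x / self.length


@dataclass
class CoronaryTree:
    """Forest of two large-artery trees (left: LMCA..., right: RCA...)."""

    segments: Dict[str, VesselSegment]
    roots: List[str]

    def __getitem__(self, name: str) -> VesselSegment:
        return self.segments[name]

    def __contains__(self, name: str) -> bool:
        return name in self.segments

    @property
    def terminals(self) -> List[str]:
        return [s.name for s in self.segments.values() if s.terminal]

    def side(self, name: str) -> str:
        """Which root tree ('left' or 'right') a segment belongs to."""
        seg = self.segments[name]
        while seg.parent is not None:
            seg = self.segments[seg.parent]
        return "right" if seg.name == "RCA" else "left"

    def validate(self) -> None:
        for seg in self.segments.values():
            for d in seg.daughters:
                if d not in self.segments:
                    raise ValueError(f"{seg.name}: unknown daughter {d}")
                if self.segments[d].parent != seg.name:
                    raise ValueError(f"inconsistent parent link for {d}")
            if seg.parent is None and seg.name not in self.roots:
                raise ValueError(f"orphan segment {seg.name}")
        # cycle check via root reachability
        seen = set()
        stack = list(self.roots)
        while stack:
            name = stack.pop()
            if name in seen:
                raise ValueError(f"cycle in topology at {name}")
            seen.add(name)
            stack.extend(self.segments[name].daughters)
        if seen != set(self.segments):
            missing = set(self.segments) - seen
            raise ValueError(f"segments unreachable from roots: {sorted(missing)}")


REQUIRED_COLUMNS = ["name", "length_mm", "r_prox_mm", "r_dist_mm", "parent"]


def packaged_table_path():
    """Path to the packaged measured-geometry table (17 segments)."""
    return resources.files("corowave.data") / "table1.csv"


def load_vessel_table(path=None) -> CoronaryTree:
    """Read a comma-delimited vessel table into a :class:`CoronaryTree`.

    Columns: name, length_mm, r_prox_mm, r_dist_mm, parent (blank parent
    marks a root).  Dimensions are converted mm -> cm.  The packaged
    measured table is used when ``path`` is None.
    """
    if path is None:
        path = packaged_table_path()
    df = pd.read_csv(path, dtype={"name": str, "parent": str}, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"geometry table missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("no segments in geometry table")

    segments: Dict[str, VesselSegment] = {}
    for row in df.itertuples(index=False):
        name = row.name.strip()
        parent = row.parent.strip() or None
        length = float(row.length_mm) / 10.0
        r_prox = float(row.r_prox_mm) / 10.0
        r_dist = float(row.r_dist_mm) / 10.0
        if name in segments:
            raise ValueError(f"duplicate segment {name}")
        segments[name] = VesselSegment(
            name=name,
            length=length,
            r_prox=r_prox,
            r_dist=r_dist,
            parent=parent,
            supply_location=SUPPLY_LOCATIONS.get(name),
        )
    roots = []
    for seg in segments.values():
        if seg.parent is None:
            roots.append(seg.name)
        else:
            if seg.parent not in segments:
                raise ValueError(f"orphan segment {seg.name}: parent {seg.parent} unknown")
            segments[seg.parent].daughters.append(seg.name)
    tree = CoronaryTree(segments=segments, roots=roots)
    tree.validate()
    return tree


def split_trifurcation(
    tree: CoronaryTree, params: Optional[TrifurcationParams] = None
) -> CoronaryTree:
    """Replace the LMCA trifurcation (LAD, LCX, DIAG) by two bifurcations.

    A short untapered intermediate segment takes over LAD and LCX, so
    LMCA's daughters become {DIAG, intermediate} and every internal node
    of the network is binary.  The intermediate radius is the printed
    anatomical value (0.185 cm) rather than a radius-exponent
    recomputation, which does not reproduce it; both are configurable.
    """
    import copy

    params = params or TrifurcationParams()
    tree = copy.deepcopy(tree)
    if "LMCA" not in tree:
        raise ValueError("LMCA not found in tree")
    lmca = tree["LMCA"]
    if len(lmca.daughters) != 3:
        raise ValueError(
            f"LMCA has {len(lmca.daughters)} daughters; expected a trifurcation"
        )
    keep = [d for d in lmca.daughters if d == "DIAG"]
    moved = [d for d in lmca.daughters if d != "DIAG"]
    if len(moved) != 2:
        raise ValueError(f"expected exactly two non-DIAG daughters, got {moved}")
    interm = VesselSegment(
        name=params.name,
        length=params.length,
        r_prox=params.radius,
        r_dist=params.radius,
        parent="LMCA",
        daughters=moved,
    )
    if interm.name in tree.segments:
        raise ValueError(f"segment name {interm.name} already used")
    tree.segments[interm.name] = interm
    for d in moved:
        tree.segments[d].parent = interm.name
    lmca.daughters = keep + [interm.name]
    tree.validate()
    return tree


def check_branching_relations(params: StructuredTreeParams) -> Dict[str, float]:
    """Residuals of the structured-tree branching identities.

    Returns the absolute residuals of
      * the radius-exponent closure  alpha^xi + beta^xi = 1,
      * the area ratio              eta = (1 + gamma) (1 + gamma^{xi/2})^{-2/xi},
      * the asymmetry ratio         gamma = (beta/alpha)^2,
    evaluated at the tabulated values.  The printed parameter set is
    mutually consistent only to ~2%, so these are reported, not enforced.
    """
    a, b, xi = params.alpha, params.beta, params.xi
    closure = a**xi + b**xi
    gamma_ab = (b / a) ** 2
    eta_pred = (1.0 + params.gamma) * (1.0 + params.gamma ** (xi / 2.0)) ** (-2.0 / xi)
    return {
        "radius_exponent_closure": abs(closure - 1.0),
        "area_ratio": abs(params.eta - eta_pred),
        "asymmetry_ratio": abs(params.gamma - gamma_ab),
        "alpha_xi_plus_beta_xi": closure,
        "gamma_from_alpha_beta": gamma_ab,
        "eta_from_gamma": eta_pred,
    }


def alpha_beta_from_exponent(xi: float, gamma: float) -> Tuple[float, float]:
    """Daughter scale factors implied by the radius exponent and asymmetry.

    From r_p^xi = r_d1^xi + r_d2^xi with gamma = (r_d2/r_d1)^2:
    alpha = (1 + gamma^{xi/2})^{-1/xi}, beta = alpha sqrt(gamma).
    Used when a scenario overrides xi (e.g. rarefaction), so that the
    branching ratios remain consistent with the exponent.
    """
    alpha = (1.0 + gamma ** (xi / 2.0)) ** (-1.0 / xi)
    return alpha, alpha * math.sqrt(gamma)


def scale_tree(tree: CoronaryTree, scale: float, lcx_only: bool = False) -> CoronaryTree:
    """Uniformly scale vessel lengths and radii (whole tree or LCX only)."""
    import copy

    if scale <= 0:
        raise ValueError("scale must be positive")
    out = copy.deepcopy(tree)
    for seg in out.segments.values():
        if lcx_only and seg.name != "LCX":
            continue
        seg.length *= scale
        seg.r_prox *= scale
        seg.r_dist *= scale
    return out


def structured_tree_radii(
    r_root: float, params: StructuredTreeParams
) -> Dict[Tuple[int, int], float]:
    """Radius lattice of a structured tree rooted at ``r_root``.

    Keys are (number of alpha-steps, number of beta-steps); values are the
    radii alpha^i beta^j r_root of every vessel with radius >= r_min.
    The lattice is downward-closed by construction.  Vessel length is
    ``l_rr`` times radius.  Returns an empty map if r_root < r_min.
    """
    if r_root <= 0:
        raise ValueError(f"non-positive root radius {r_root}")
    radii: Dict[Tuple[int, int], float] = {}
    if r_root < params.r_min:
        return radii
    la, lb = math.log(params.alpha), math.log(params.beta)
    lr = math.log(params.r_min / r_root)
    i_max = int(math.floor(lr / la + 1e-12))
    for i in range(i_max + 1):
        rem = lr - i * la
        j_max = int(math.floor(rem / lb + 1e-12))
        for j in range(j_max + 1):
            radii[(i, j)] = (params.alpha**i) * (params.beta**j) * r_root
    return radii
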