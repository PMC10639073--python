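"""Active-site geometric descriptors for ribonucleotide discrimination.

The order parameters:

* **sensor angle** ("N828 shift") — the angle at the sensor side-chain Cγ
  between its Cα and the O2B β-phosphate oxygen of the incoming nucleotide.
  A wide angle (near 160°) is the *locked* sensor conformation, stabilised by
  a loose H-bond to the β-phosphate when a dNTP is bound; a decreased angle
  is the *unlocked* conformation seen with ribonucleotides.
* **gate distance** ("sugar ring—Y645 distance") — Cδ1 of the steric-gate
  tyrosine to C2′ of the incoming nucleotide's sugar; consistently ~0.6 Å
  larger for a ribonucleotide, whose 2′-OH clashes with the gate.
* **catalytic gap** — backbone Cα of catalytic D877 to the Y645 hydroxyl
  oxygen; reports the void opened by loosening the gate's neighbour (M644G).
* **per-atom displacement** between two liganded structures after scheme
  superposition, and **base-pair coplanarity** of the nascent pair.

All descriptors are invariant under proper rigid motion of the whole
structure; angles are degrees, distances Å.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import UnsupportedResidueError
from .sitemap import SiteMap
from .structure_io import AtomSelector, Structure, select_atoms
from .superposition import AlignmentScheme, align_structures

__all__ = [
    "DescriptorValue",
    "DEFAULT_LOCKED_THRESHOLD",
    "SENSOR_SIDE_CHAIN_ATOMS",
    "PURINE_RING", "PYRIMIDINE_RING",
    "angle_deg",
    "sensor_angle", "gate_distance", "catalytic_gap",
    "atom_displacement", "DisplacementReport",
    "base_pair_coplanarity", "classify_state",
]

#: Locked/unlocked classification boundary, degrees.  The two modes are only
#: characterised qualitatively (locked near 160°, unlocked decidedly lower),
#: so the boundary is a visible configuration item, never hard-coded in
#: analysis code.
DEFAULT_LOCKED_THRESHOLD = 140.0

#: Side-chain atoms reported when quantifying the sensor shift; ASN and VAL
#: variants both covered.
SENSOR_SIDE_CHAIN_ATOMS = ("CB", "CG", "OD1", "ND2", "CG1", "CG2")

PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass(frozen=True)
class DescriptorValue:
    kind: str
    value: float
    units: str
    atoms_used: tuple = ()


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Interior angle ∠(a, vertex, c) in degrees, clipped into [0, 180]."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(c, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("zero-length arm: angle undefined")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def sensor_angle(s: Structure, site: SiteMap) -> float:
    """Sensor-state order parameter: angle Cα–Cγ···O2B at the sensor Cγ."""
    addr = site.address("sensor")
    ca = site.atom(s, "sensor", "CA").pos
    # VAL sensors carry CG1 in place of the amide CG.
    if s.has_atom(addr.chain, addr.res_num, "CG"):
        cg = s.atom(addr.chain, addr.res_num, "CG").pos
    elif s.has_atom(addr.chain, addr.res_num, "CG1"):
        cg = s.atom(addr.chain, addr.res_num, "CG1").pos
    else:
        res = next((a.res_name for a in s.atoms
                    if a.chain == addr.chain and a.res_num == addr.res_num), "?")
        raise UnsupportedResidueError(
            f"sensor residue {res} {addr.res_num} has no Cγ; angle undefined")
    o2b = site.atom(s, "nucleotide", "O2B").pos
    return angle_deg(ca, cg, o2b)


def gate_distance(s: Structure, site: SiteMap) -> float:
    """Steric-gate Cδ1 to nucleotide C2′ distance (Å)."""
    cd1 = site.atom(s, "steric_gate", "CD1").pos
    c2p = site.atom(s, "nucleotide", "C2'").pos
    return float(np.linalg.norm(cd1 - c2p))


def catalytic_gap(s: Structure, site: SiteMap) -> float:
    """D877 backbone Cα to Y645 hydroxyl oxygen distance (Å)."""
    ca = site.atom(s, "catalytic_1", "CA").pos
    oh = site.atom(s, "steric_gate", "OH").pos
    return float(np.linalg.norm(ca - oh))


@dataclass
class DisplacementReport:
    """Per-atom displacements (Å) of target atoms after scheme superposition."""

    per_atom: list[tuple[tuple[str, int, str], float]]
    fit_rmsd: float
    scheme: str
    summary: dict = field(init=False)

    def __post_init__(self):
        vals = [d for _, d in self.per_atom]
        self.summary = {
            "max": float(max(vals)) if vals else float("nan"),
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "n_atoms": len(vals),
        }

    @property
    def max(self) -> float:
        return self.summary["max"]

    @property
    def mean(self) -> float:
        return self.summary["mean"]


def atom_displacement(ref: Structure, mov: Structure,
                      scheme: str | AlignmentScheme, target: AtomSelector,
                      site_ref: SiteMap | None = None,
                      site_mov: SiteMap | None = None) -> DisplacementReport:
    """Superimpose ``mov`` on ``ref`` by the scheme, then measure the Euclidean
    displacement of every target atom matched by address between the two."""
    moved, fit = align_structures(ref, mov, scheme, site_ref, site_mov)
    ref_atoms = {a.address: a for a in select_atoms(ref, target)}
    per_atom = []
    for a in select_atoms(moved, target):
        r = ref_atoms.get(a.address)
        if r is not None:
            per_atom.append((a.address, float(np.linalg.norm(a.pos - r.pos))))
    return DisplacementReport(per_atom, fit.rmsd, fit.scheme)


def _ring_atoms(s: Structure, chain: str, res_num: int) -> np.ndarray:
    names = set(PURINE_RING) | set(PYRIMIDINE_RING)
    pts = [a.pos for a in s.atoms
           if a.chain == chain and a.res_num == res_num and a.name in names]
    return np.array(pts) if pts else np.empty((0, 3))


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    # Total-least-squares plane: normal is the smallest right singular vector.
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def base_pair_coplanarity(s: Structure, site: SiteMap) -> float:
    """Angle (degrees) between best-fit planes of the templating base and the
    incoming base's ring atoms; 0° means a planar nascent pair."""
    t_addr = site.address("template_base")
    n_addr = site.address("nucleotide")
    t_ring = _ring_atoms(s, t_addr.chain, t_addr.res_num)
    n_ring = _ring_atoms(s, n_addr.chain, n_addr.res_num)
    for label, ring in (("template", t_ring), ("incoming", n_ring)):
        if ring.shape[0] < 3:
            raise ValueError(f"{label} base has fewer than 3 ring atoms")
    n1 = _plane_normal(t_ring)
    n2 = _plane_normal(n_ring)
    ang = math.degrees(math.acos(np.clip(abs(np.dot(n1, n2)), 0.0, 1.0)))
    return ang


def classify_state(angle: float, threshold: float = DEFAULT_LOCKED_THRESHOLD) -> str:
    """``locked`` iff angle ≥ threshold, else ``unlocked``."""
    if not (0.0 <= angle <= 180.0):
        raise ValueError(f"sensor angle {angle} outside [0, 180] degrees")
    return "locked" if angle >= threshold else "unlocked"
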