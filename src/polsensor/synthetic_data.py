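"""Seeded generators of idealized active-site fixtures.

The generators emulate the geometric situations the analysis modules are
built to measure — a polymerase active site with a steric-gate tyrosine,
finger-domain sensor, catalytic aspartates and an incoming (deoxy)ribo-
nucleotide; pairs of liganded structures differing by a sensor/catalytic
shift; two-state sensor-angle trajectories; and donor–acceptor geometries
for the H-bond auditor.  Fixtures are minimal (tens of atoms) rather than
whole-protein models: descriptor and H-bond logic only ever addresses named
atoms, so minimality is sufficient and keeps every test sub-second.

Construction is exact: each requested descriptor value is realized
analytically (the sensor Cα and the nucleotide O2B sit on a circle of fixed
arm length about the sensor Cγ; the gate Cδ1 is placed at the requested
distance from C2′ along a fixed axis), so re-measuring a noiseless fixture
returns the construction parameter to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConstructionError
from .hbond import HBondCriteria, RELAXED_DEFAULT, STRICT_DEFAULT
from .sitemap import default_site_map, SiteMap
from .structure_io import AtomRecord, Structure
from .trajectory_analysis import Trajectory

__all__ = [
    "SiteParams", "TwoStateParams",
    "make_active_site", "make_structure_pair",
    "make_two_state_trajectory", "make_hbond_fixture",
]

# -- construction constants (documented so fixtures are reproducible) -------

SENSOR_CG = np.array([-4.0, 2.0, 0.0])   # sensor Cγ (circle centre)
SENSOR_ARM = 2.5                          # Å, Cγ→Cα and Cγ→O2B arm length
C2P_OFFSET = np.array([0.0, 0.0, 3.0])    # C2' relative to O2B
GATE_AXIS = np.array([0.0, 0.0, 1.0])     # Cδ1 placed along this axis from C2'
GAP_AXIS = np.array([0.0, 0.6, 0.8])      # Y645 OH placed along this from D877 Cα
SHIFT_AXIS = np.array([0.0, 0.6, 0.8])    # displacement direction in pairs

#: Fixed scaffold Cα positions (chain A) for every residue the alignment
#: presets address; well spread and non-collinear by construction.
SCAFFOLD_CA = {
    556: (12.0, -8.0, 4.0),
    640: (8.0, 6.0, -2.0),
    644: (4.0, -4.0, 6.0),
    645: (0.0, 0.0, 8.0),
    831: (-6.0, 10.0, 2.0),
    833: (-10.0, -6.0, -4.0),
    836: (14.0, 10.0, 8.0),
    877: (6.0, -12.0, -6.0),
}

TEMPLATE_RING_CENTER = np.array([0.0, -10.0, 0.0])
INCOMING_RING_CENTER = np.array([3.0, -10.0, 0.0])
RING_RADIUS = 1.4

PURINE_RING = ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass(frozen=True)
class SiteParams:
    """Parameters of one idealized active-site fixture."""

    sensor_identity: str = "ASN"   # ASN | VAL
    neighbor_identity: str = "MET"  # MET | GLY
    sugar: str = "deoxy"           # deoxy | ribo
    sensor_angle: float = 160.0    # degrees, locked-mode value
    gate_distance: float = 3.4     # Å
    catalytic_gap: float = 8.0     # Å
    coplanarity: float = 0.0       # degrees
    seed: int = 0

    def __post_init__(self):
        if self.sensor_identity not in ("ASN", "VAL"):
            raise ConstructionError(f"sensor must be ASN or VAL, got {self.sensor_identity}")
        if self.neighbor_identity not in ("MET", "GLY"):
            raise ConstructionError(f"neighbor must be MET or GLY, got {self.neighbor_identity}")
        if self.sugar not in ("deoxy", "ribo"):
            raise ConstructionError(f"sugar must be deoxy or ribo, got {self.sugar}")
        if not (0.0 <= self.sensor_angle <= 180.0):
            raise ConstructionError("sensor_angle outside [0, 180] degrees")
        for name in ("gate_distance", "catalytic_gap"):
            if getattr(self, name) <= 0:
                raise ConstructionError(f"{name} must be positive")
        if not (0.0 <= self.coplanarity <= 90.0):
            raise ConstructionError("coplanarity must lie in [0, 90] degrees")


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state mixture for synthetic sensor-angle trajectories.

    Defaults put the locked mode at 160° and separate ribo from deoxy gate
    distances by 0.6 Å; mode SDs (8° and 10°) are conventional choices —
    no measured widths exist for the modes — and fully configurable.
    """

    n_frames: int = 24000
    p_locked: float = 0.7
    locked_mean: float = 160.0
    locked_sd: float = 8.0
    unlocked_mean: float = 110.0
    unlocked_sd: float = 10.0
    gate_mean: float = 3.4
    gate_sd: float = 0.3
    ribo_gate_offset: float = 0.6
    frame_interval: float = 12.5  # ps
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_locked <= 1.0):
            raise ConstructionError("p_locked must lie in [0, 1]")
        if self.locked_sd <= 0 or self.unlocked_sd <= 0 or self.gate_sd <= 0:
            raise ConstructionError("mode SDs must be positive")
        if self.n_frames < 1:
            raise ConstructionError("n_frames must be ≥ 1")


def o2b_position(angle_deg: float) -> np.ndarray:
    """O2B on the sensor circle: the Cα–Cγ···O2B angle equals ``angle_deg``."""
    theta = math.radians(angle_deg)
    return SENSOR_CG + SENSOR_ARM * np.array([math.cos(theta), math.sin(theta), 0.0])


def cd1_position(gate_distance: float, c2p: np.ndarray) -> np.ndarray:
    return c2p + gate_distance * GATE_AXIS


def _ring(center: np.ndarray, names: tuple[str, ...], tilt_deg: float) -> list[tuple[str, np.ndarray]]:
    """Planar ring of atoms around ``center``; plane normal tilted about x by
    ``tilt_deg`` away from z, so two rings built with tilts 0 and c meet at a
    dihedral of exactly c degrees."""
    t = math.radians(tilt_deg)
    e1 = np.array([1.0, 0.0, 0.0])
    e2 = np.array([0.0, math.cos(t), math.sin(t)])
    out = []
    for k, name in enumerate(names):
        phi = 2.0 * math.pi * k / len(names)
        out.append((name, center + RING_RADIUS * (math.cos(phi) * e1 + math.sin(phi) * e2)))
    return out


def make_active_site(p: SiteParams) -> tuple[Structure, SiteMap]:
    """Minimal active-site Structure realizing each requested descriptor.

    Returns the structure and a matching SiteMap.  Deterministic: the same
    parameters (including seed) give bit-identical output.
    """
    atoms: list[AtomRecord] = []
    serial = 1

    def add(name, res_name, chain, res_num, pos, element="C", is_het=False):
        nonlocal serial
        atoms.append(AtomRecord(serial, name, "", res_name, chain, res_num, "",
                                np.asarray(pos, float), 1.0, element, is_het))
        serial += 1

    ca645 = np.array(SCAFFOLD_CA[645])
    ca877 = np.array(SCAFFOLD_CA[877])
    o2b = o2b_position(p.sensor_angle)
    c2p = o2b + C2P_OFFSET
    cd1 = cd1_position(p.gate_distance, c2p)
    oh = ca877 + p.catalytic_gap * GAP_AXIS / np.linalg.norm(GAP_AXIS)

    # protein chain A ------------------------------------------------------
    for res_num, res_name, extras in (
        (556, "GLY", ()),
        (640, "ASP", (("CB", (1.1, 0.4, -0.6)), ("CG", (1.9, -0.5, -1.2)))),
        (644, p.neighbor_identity, () if p.neighbor_identity == "GLY"
         else (("CB", (0.9, 0.9, 0.2)), ("SD", (2.4, 1.6, 0.7)))),
        (833, "LEU", ()),
        (836, "LYS", ()),
    ):
        ca = np.array(SCAFFOLD_CA[res_num])
        add("CA", res_name, "A", res_num, ca)
        for name, off in extras:
            el = "S" if name == "SD" else "C"
            add(name, res_name, "A", res_num, ca + np.array(off), el)

    # steric gate Y645: CA on scaffold; CD1 and OH carry the constructed
    # gate-distance and catalytic-gap geometry (fixture minimality — no
    # attempt at internally consistent tyrosine stereochemistry).
    add("CA", "TYR", "A", 645, ca645)
    add("CB", "TYR", "A", 645, ca645 + np.array([0.9, 0.9, -0.8]))
    add("CD1", "TYR", "A", 645, cd1)
    add("CZ", "TYR", "A", 645, oh + np.array([0.0, -0.8, -1.1]))
    add("OH", "TYR", "A", 645, oh, "O")

    # sensor 828
    ca828 = SENSOR_CG + SENSOR_ARM * np.array([1.0, 0.0, 0.0])
    add("CA", p.sensor_identity, "A", 828, ca828)
    add("CB", p.sensor_identity, "A", 828, SENSOR_CG + np.array([1.2, -0.8, 0.4]))
    if p.sensor_identity == "ASN":
        add("CG", "ASN", "A", 828, SENSOR_CG)
        add("OD1", "ASN", "A", 828, SENSOR_CG + np.array([-0.6, -1.0, 0.8]), "O")
        add("ND2", "ASN", "A", 828, SENSOR_CG + np.array([0.6, 1.0, -1.0]), "N")
    else:
        # VAL sensor: CG1 sits on the circle centre so the angle stays defined.
        add("CG1", "VAL", "A", 828, SENSOR_CG)
        add("CG2", "VAL", "A", 828, SENSOR_CG + np.array([0.5, 1.1, 0.9]))

    # stack Y831
    ca831 = np.array(SCAFFOLD_CA[831])
    add("CA", "TYR", "A", 831, ca831)

    # catalytic D877
    add("CA", "ASP", "A", 877, ca877)
    add("CB", "ASP", "A", 877, ca877 + np.array([1.0, 0.7, 0.6]))
    add("OD1", "ASP", "A", 877, ca877 + np.array([2.1, 1.1, 1.4]), "O")

    # templating base, chain T (purine, tilt 0)
    for name, pos in _ring(TEMPLATE_RING_CENTER, PURINE_RING, 0.0):
        add(name, "DA", "T", 1, pos, "N" if name.startswith("N") else "C")

    # incoming nucleotide, chain N (pyrimidine base tilted by the requested
    # coplanarity angle, plus sugar and β-phosphate atoms)
    code = ("UTP" if p.sugar == "ribo" else "TTP")
    for name, pos in _ring(INCOMING_RING_CENTER, PYRIMIDINE_RING, p.coplanarity):
        add(name, code, "N", 1, pos, "N" if name.startswith("N") else "C", True)
    add("C1'", code, "N", 1, c2p + np.array([1.5, 0.0, 0.3]), "C", True)
    add("C2'", code, "N", 1, c2p, "C", True)
    add("C3'", code, "N", 1, c2p + np.array([0.1, -1.4, 0.4]), "C", True)
    add("O3'", code, "N", 1, c2p + np.array([0.6, -2.3, 0.9]), "O", True)
    if p.sugar == "ribo":
        add("O2'", code, "N", 1, c2p + np.array([-0.7, 1.1, 0.6]), "O", True)
    add("PB", code, "N", 1, o2b + np.array([-1.0, -0.9, -0.4]), "P", True)
    add("O2B", code, "N", 1, o2b, "O", True)

    structure = Structure(atoms, 1, f"synthetic:{p.sensor_identity}828-{code}")
    site = default_site_map(sugar=p.sugar, nucleotide_code=code)
    return structure, site


def make_structure_pair(base: SiteParams, sensor_shift: float = 0.0,
                        d877_shift: float = 0.0) -> tuple[Structure, Structure, SiteMap]:
    """Two copies of an active site differing only by a rigid displacement of
    the sensor side chain (by ``sensor_shift`` Å) and/or the D877 Cα (by
    ``d877_shift`` Å); all other atoms, including every finger_palm scheme
    Cα, are untouched.

    Measure the sensor shift with the ``palm`` scheme (its atoms never move
    here) and the D877 Cα shift with ``finger_palm`` (877 is a palm-scheme
    atom, so the palm fit would absorb part of that shift).
    """
    if sensor_shift < 0 or d877_shift < 0:
        raise ConstructionError("shifts must be non-negative")
    s1, site = make_active_site(base)
    u = SHIFT_AXIS / np.linalg.norm(SHIFT_AXIS)
    side_chain = {"CB", "CG", "CG1", "CG2", "OD1", "ND2"}
    sensor_addr = site.address("sensor")
    atoms2 = []
    for a in s1.atoms:
        pos = a.pos.copy()
        if (a.chain == sensor_addr.chain and a.res_num == sensor_addr.res_num
                and a.name in side_chain):
            pos = pos + sensor_shift * u
        elif (a.chain == site.address("catalytic_1").chain
              and a.res_num == site.address("catalytic_1").res_num
              and a.name == "CA"):
            pos = pos + d877_shift * u
        atoms2.append(a.moved(pos))
    s2 = Structure(atoms2, 1, s1.source_id + ":shifted")
    return s1, s2, site


def make_two_state_trajectory(p: TwoStateParams, site: SiteParams | None = None,
                              replica_id: str = "r1") -> Trajectory:
    """Trajectory whose sensor angle follows a locked/unlocked normal mixture
    and whose gate distance is normal (plus the ribo offset when the site is
    ribonucleotide-bound).

    Per frame the state is Bernoulli(p_locked) and the angle is drawn from
    that state's normal, clipped to [0, 180]; clip events are counted in
    ``trajectory.metadata`` and never silently resampled.  Identical seeds
    with ribo vs deoxy sugars consume the random stream identically, so the
    two gate series differ by exactly the ribo offset frame by frame.
    """
    if site is None:
        site = SiteParams()
    topo, sitemap = make_active_site(site)
    rng = np.random.default_rng(p.seed)
    n = p.n_frames

    states = rng.random(n) < p.p_locked
    locked_draws = rng.normal(p.locked_mean, p.locked_sd, n)
    unlocked_draws = rng.normal(p.unlocked_mean, p.unlocked_sd, n)
    angles = np.where(states, locked_draws, unlocked_draws)
    n_angle_clips = int(np.sum((angles < 0) | (angles > 180)))
    angles = np.clip(angles, 0.0, 180.0)

    gates = rng.normal(p.gate_mean, p.gate_sd, n)
    if site.sugar == "ribo":
        gates = gates + p.ribo_gate_offset
    n_gate_clips = int(np.sum(gates < 1e-6))
    gates = np.clip(gates, 1e-6, None)

    coords = np.broadcast_to(topo.coords, (n, len(topo), 3)).copy()
    i_o2b = sitemap.atom_index(topo, "nucleotide", "O2B")
    i_c2p = sitemap.atom_index(topo, "nucleotide", "C2'")
    i_cd1 = sitemap.atom_index(topo, "steric_gate", "CD1")
    theta = np.radians(angles)
    coords[:, i_o2b, :] = SENSOR_CG + SENSOR_ARM * np.stack(
        [np.cos(theta), np.sin(theta), np.zeros(n)], axis=1)
    coords[:, i_cd1, :] = coords[:, i_c2p, :] + gates[:, None] * GATE_AXIS

    return Trajectory(topo, coords, p.frame_interval, replica_id,
                      metadata={"n_angle_clips": n_angle_clips,
                                "n_gate_clips": n_gate_clips,
                                "states": states,
                                "sitemap": sitemap})


# ---------------------------------------------------------------------------
# H-bond audit fixtures

_PAIR_SPACING = 50.0  # Å between constructed donor/acceptor pairs


def _pair_geometry(category: str, strict: HBondCriteria,
                   relaxed: HBondCriteria) -> tuple[float, float]:
    """(distance, donor angle) built to land in the requested verdict class."""
    if category == "strict":
        return 0.8 * strict.max_da, (strict.min_angle + 180.0) / 2.0
    if category == "relaxed_only":
        if relaxed.max_da > strict.max_da:
            return ((strict.max_da + relaxed.max_da) / 2.0,
                    (strict.min_angle + 180.0) / 2.0)
        if relaxed.min_angle < strict.min_angle:
            return 0.8 * strict.max_da, (relaxed.min_angle + strict.min_angle) / 2.0
        raise ConstructionError(
            "relaxed_only pairs are unrealizable when strict and relaxed "
            "criteria coincide")
    if category == "fail":
        return relaxed.max_da + 1.0, (strict.min_angle + 180.0) / 2.0
    raise ValueError(category)


def make_hbond_fixture(n_strict: int, n_relaxed_only: int, n_fail: int,
                       include_water_bridge: bool = False,
                       strict: HBondCriteria = STRICT_DEFAULT,
                       relaxed: HBondCriteria = RELAXED_DEFAULT,
                       seed: int = 0):
    """Structure + proposed-pair list whose audit partition is exactly
    (n_strict, n_relaxed_only, n_fail) under the given criteria.

    Each pair is an isolated serine OG donor (CB antecedent) and a carbonyl
    O acceptor, placed 50 Å from its neighbours so pairs cannot interact.
    With ``include_water_bridge`` one failing pair is rebuilt at twice a
    bridgeable leg length and gains a water O at its midpoint, giving exactly
    one water-mediated flag.  Pair order is shuffled with the seed.
    """
    for name, v in (("n_strict", n_strict), ("n_relaxed_only", n_relaxed_only),
                    ("n_fail", n_fail)):
        if v < 0:
            raise ConstructionError(f"{name} must be ≥ 0")
    if include_water_bridge and n_fail < 1:
        raise ConstructionError("a water bridge needs at least one failing pair")

    categories = (["strict"] * n_strict + ["relaxed_only"] * n_relaxed_only
                  + ["fail"] * n_fail)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(categories))
    categories = [categories[i] for i in order]

    atoms: list[AtomRecord] = []
    pairs = []
    serial = 1
    bridged = False

    def add(name, res_name, chain, res_num, pos, element, is_het=False):
        nonlocal serial
        atoms.append(AtomRecord(serial, name, "", res_name, chain, res_num, "",
                                np.asarray(pos, float), 1.0, element, is_het))
        serial += 1

    # mark the last failing pair (in shuffled order) for the water bridge
    bridge_at = None
    if include_water_bridge:
        bridge_at = max(i for i, c in enumerate(categories) if c == "fail")

    for i, cat in enumerate(categories):
        base = np.array([_PAIR_SPACING * i, 0.0, 0.0])
        if i == bridge_at:
            # too long for a direct bond even relaxed, but bridgeable
            d = 1.4 * relaxed.max_da
            theta = (strict.min_angle + 180.0) / 2.0
        else:
            d, theta = _pair_geometry(cat, strict, relaxed)
        phi = math.radians(180.0 - theta)
        cb = base
        og = base + np.array([1.43, 0.0, 0.0])
        acc = og + d * np.array([math.cos(phi), math.sin(phi), 0.0])
        add("CB", "SER", "D", i + 1, cb, "C")
        add("OG", "SER", "D", i + 1, og, "O")
        add("O", "GLY", "E", i + 1, acc, "O")
        if i == bridge_at:
            add("O", "HOH", "W", i + 1, (og + acc) / 2.0, "O", True)
            bridged = True
        pairs.append((("D", i + 1, "OG"), ("E", i + 1, "O")))

    assert bridged == include_water_bridge
    return Structure(atoms, 1, "synthetic:hbond-fixture"), pairs
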