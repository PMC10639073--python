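"""Geometric hydrogen-bond audit with strict and relaxed criteria.

The audit grades an explicitly proposed list of donor–acceptor pairs (the
contacts a "polar filter" mechanism would require) on heavy-atom geometry
alone, since crystal structures carry no hydrogens: the donor–acceptor
distance must stay under a ceiling and the angle at the donor — measured
antecedent–donor···acceptor, the antecedent being the heavy atom bonded to
the donor — must stay above a floor.  Two criteria sets are evaluated at
once; the relaxed set must dominate the strict set (larger ceiling, lower
floor), which makes every strict pass a relaxed pass by construction.
Pairs failing even relaxed criteria are additionally checked for a bridging
water that contacts both partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ChemistryTableError, CriteriaConfigError, MissingAtomError
from .descriptors import angle_deg
from .structure_io import Structure, WATER_RES_NAMES

__all__ = [
    "HBondCriteria", "HBondCandidate", "HBondCall",
    "STRICT_DEFAULT", "RELAXED_DEFAULT", "DONOR_ANTECEDENTS",
    "enumerate_candidates", "evaluate_hbond", "water_mediated", "audit_network",
    "AuditResult",
]

Address = tuple[str, int, str]  # (chain, res_num, atom_name)


@dataclass(frozen=True)
class HBondCriteria:
    """Donor–acceptor distance ceiling (Å) and donor-angle floor (degrees)."""

    max_da: float
    min_angle: float
    label: str = "strict"

    def __post_init__(self):
        if self.max_da <= 0:
            raise ValueError("max_da must be positive")
        if not (0.0 <= self.min_angle <= 180.0):
            raise ValueError("min_angle must lie in [0, 180]")

    def passes(self, da: float, angle: float) -> bool:
        return da <= self.max_da and angle >= self.min_angle


#: Default thresholds.  Strict follows common crystallographic practice
#: (≤3.5 Å, donor angle ≥120°); relaxed slackens by +0.4 Å / −20°, mirroring
#: the relax convention of interactive H-bond finders.  Always configurable
#: and always echoed in report headers.
STRICT_DEFAULT = HBondCriteria(3.5, 120.0, "strict")
RELAXED_DEFAULT = HBondCriteria(3.9, 100.0, "relaxed")

#: (res_name, donor atom) -> antecedent heavy atom.  ``"*"`` matches any
#: residue (backbone amide, nucleotide sugar/base donors).  Extensible per
#: call; deliberately covers only donors the audits address.
DONOR_ANTECEDENTS: dict[tuple[str, str], str] = {
    ("SER", "OG"): "CB",
    ("THR", "OG1"): "CB",
    ("TYR", "OH"): "CZ",
    ("ASN", "ND2"): "CG",
    ("GLN", "NE2"): "CD",
    ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD",
    ("ARG", "NH1"): "CZ",
    ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG",
    ("HIS", "NE2"): "CD2",
    ("TRP", "NE1"): "CD1",
    ("*", "N"): "CA",       # backbone amide
    ("*", "O2'"): "C2'",    # ribose 2'-OH
    ("*", "O3'"): "C3'",    # sugar 3'-OH
    ("*", "N6"): "C6",      # adenine amino
    ("*", "N4"): "C4",      # cytosine amino
    ("*", "N2"): "C2",      # guanine amino
    ("*", "N1"): "C2",      # guanine N1-H (imino)
    ("*", "N3"): "C2",      # uracil/thymine N3-H
}


@dataclass(frozen=True)
class HBondCandidate:
    donor: Address
    donor_antecedent: Address
    acceptor: Address
    measured_da: float
    measured_angle: float

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor are the same atom")


@dataclass(frozen=True)
class HBondCall:
    candidate: HBondCandidate
    verdict: str  # strict | relaxed_only | fail | water_mediated
    bridging_water: Address | None = None


def _antecedent_name(res_name: str, donor_name: str,
                     table: dict[tuple[str, str], str]) -> str:
    if (res_name, donor_name) in table:
        return table[(res_name, donor_name)]
    if ("*", donor_name) in table:
        return table[("*", donor_name)]
    raise ChemistryTableError(
        f"no antecedent entry for donor {donor_name} of residue {res_name}")


def enumerate_candidates(s: Structure, pairs: list[tuple[Address, Address]],
                         antecedents: dict[tuple[str, str], str] | None = None,
                         ) -> list[HBondCandidate]:
    """Measure geometry for each proposed (donor, acceptor) address pair.

    Order is preserved; missing atoms raise :class:`MissingAtomError`, an
    unresolvable donor antecedent raises :class:`ChemistryTableError`.
    """
    table = DONOR_ANTECEDENTS if antecedents is None else {**DONOR_ANTECEDENTS, **antecedents}
    out = []
    for donor_addr, acceptor_addr in pairs:
        if donor_addr == acceptor_addr:
            raise ValueError(f"donor equals acceptor: {donor_addr}")
        donor = s.atom(*donor_addr)
        acceptor = s.atom(*acceptor_addr)
        ante_name = _antecedent_name(donor.res_name, donor.name, table)
        ante_addr = (donor_addr[0], donor_addr[1], ante_name)
        if not s.has_atom(*ante_addr):
            raise MissingAtomError([ante_addr])
        ante = s.atom(*ante_addr)
        da = float(np.linalg.norm(donor.pos - acceptor.pos))
        ang = angle_deg(ante.pos, donor.pos, acceptor.pos)
        out.append(HBondCandidate(donor_addr, ante_addr, acceptor_addr, da, ang))
    return out


def _check_dominance(strict: HBondCriteria, relaxed: HBondCriteria) -> None:
    if relaxed.max_da < strict.max_da or relaxed.min_angle > strict.min_angle:
        raise CriteriaConfigError(
            f"relaxed criteria ({relaxed.max_da} Å, {relaxed.min_angle}°) do not "
            f"dominate strict ({strict.max_da} Å, {strict.min_angle}°)")


def evaluate_hbond(c: HBondCandidate, strict: HBondCriteria = STRICT_DEFAULT,
                   relaxed: HBondCriteria = RELAXED_DEFAULT) -> HBondCall:
    """Verdict: ``strict`` if both strict thresholds met, ``relaxed_only`` if
    only the relaxed set passes, otherwise ``fail``."""
    _check_dominance(strict, relaxed)
    if strict.passes(c.measured_da, c.measured_angle):
        verdict = "strict"
    elif relaxed.passes(c.measured_da, c.measured_angle):
        verdict = "relaxed_only"
    else:
        verdict = "fail"
    # Dominance makes strict ⊆ relaxed structurally true; assert anyway.
    if verdict == "strict":
        assert relaxed.passes(c.measured_da, c.measured_angle)
    return HBondCall(c, verdict)


def water_mediated(donor_addr: Address, acceptor_addr: Address, s: Structure,
                   criteria: HBondCriteria = RELAXED_DEFAULT,
                   antecedents: dict[tuple[str, str], str] | None = None,
                   ) -> Address | None:
    """Find a bridging water oxygen contacting both partners.

    Both bridge legs must satisfy the distance ceiling; the angle floor is
    applied on the partner side where an antecedent is defined (the water
    oxygen has no hydrogens in heavy-atom-only evaluation).  Among qualifying
    waters the one minimizing the summed leg distances is returned.
    """
    table = DONOR_ANTECEDENTS if antecedents is None else {**DONOR_ANTECEDENTS, **antecedents}
    donor = s.atom(*donor_addr)
    acceptor = s.atom(*acceptor_addr)
    try:
        ante_name = _antecedent_name(donor.res_name, donor.name, table)
        ante_pos = s.atom(donor_addr[0], donor_addr[1], ante_name).pos
    except (ChemistryTableError, MissingAtomError):
        ante_pos = None

    best: tuple[float, Address] | None = None
    for a in s.atoms:
        if a.res_name not in WATER_RES_NAMES or not a.name.startswith("O"):
            continue
        d1 = float(np.linalg.norm(a.pos - donor.pos))
        d2 = float(np.linalg.norm(a.pos - acceptor.pos))
        if d1 > criteria.max_da or d2 > criteria.max_da:
            continue
        if ante_pos is not None:
            ang = angle_deg(ante_pos, donor.pos, a.pos)
            if ang < criteria.min_angle:
                continue
        total = d1 + d2
        if best is None or total < best[0]:
            best = (total, a.address)
    return None if best is None else best[1]


@dataclass
class AuditResult:
    calls: list[HBondCall]
    counts: dict[str, int]
    strict_criteria: HBondCriteria
    relaxed_criteria: HBondCriteria

    def to_rows(self) -> list[dict]:
        rows = []
        for call in self.calls:
            c = call.candidate
            rows.append({
                "donor": ":".join(map(str, c.donor)),
                "acceptor": ":".join(map(str, c.acceptor)),
                "distance_A": round(c.measured_da, 3),
                "donor_angle_deg": round(c.measured_angle, 2),
                "verdict": call.verdict,
                "bridging_water": (":".join(map(str, call.bridging_water))
                                   if call.bridging_water else ""),
            })
        return rows


def audit_network(s: Structure, pairs: list[tuple[Address, Address]],
                  strict: HBondCriteria = STRICT_DEFAULT,
                  relaxed: HBondCriteria = RELAXED_DEFAULT,
                  check_water: bool = True,
                  antecedents: dict[tuple[str, str], str] | None = None,
                  ) -> AuditResult:
    """Grade every proposed pair; failing pairs are screened for a bridging
    water.  ``strict + relaxed_only + fail`` always equals ``len(pairs)``;
    water-mediated contacts are counted within ``fail`` but flagged."""
    _check_dominance(strict, relaxed)
    candidates = enumerate_candidates(s, pairs, antecedents)
    calls: list[HBondCall] = []
    counts = {"strict": 0, "relaxed_only": 0, "fail": 0, "water_mediated": 0}
    for c in candidates:
        call = evaluate_hbond(c, strict, relaxed)
        if call.verdict == "fail" and check_water:
            bridge = water_mediated(c.donor, c.acceptor, s, relaxed, antecedents)
            if bridge is not None:
                call = HBondCall(c, "fail", bridge)
                counts["water_mediated"] += 1
        counts[call.verdict] += 1
        calls.append(call)
    assert counts["strict"] + counts["relaxed_only"] + counts["fail"] == len(pairs)
    return AuditResult(calls, counts, strict, relaxed)
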