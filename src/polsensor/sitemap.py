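"""Role-based addressing of the polymerase active site.

A :class:`SiteMap` records where each functional role lives in a particular
deposition: the steric gate (Y645), the ribonucleotide sensor (N828, or V828
in the sensor-dead variant), the catalytic aspartates (D877, D640), the
neighbour whose truncation loosens the gate (M644/G644), the stacking
tyrosine (Y831), the incoming nucleotide and the templating base.  Depositions
disagree on chain naming and ligand codes, so the map is configuration, not
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .structure_io import Structure, AtomRecord

__all__ = ["SiteAddress", "SiteMap", "default_site_map"]

PROTEIN_ROLES = ("steric_gate", "sensor", "catalytic_1", "catalytic_2",
                 "neighbor", "stack")


@dataclass(frozen=True)
class SiteAddress:
    chain: str
    res_num: int


@dataclass
class SiteMap:
    """Chain + residue addresses for each active-site role."""

    steric_gate: SiteAddress
    sensor: SiteAddress
    catalytic_1: SiteAddress
    catalytic_2: SiteAddress
    neighbor: SiteAddress
    stack: SiteAddress
    nucleotide: SiteAddress
    template_base: SiteAddress
    nucleotide_code: str = "UTP"
    sugar: str = "ribo"  # deoxy | ribo
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sugar not in ("deoxy", "ribo"):
            raise ValueError(f"sugar class must be deoxy|ribo, got {self.sugar!r}")

    def address(self, role: str) -> SiteAddress:
        try:
            return getattr(self, role)
        except AttributeError:
            raise KeyError(f"unknown site role {role!r}") from None

    def atom(self, s: Structure, role: str, atom_name: str) -> AtomRecord:
        addr = self.address(role)
        return s.atom(addr.chain, addr.res_num, atom_name)

    def atom_index(self, s: Structure, role: str, atom_name: str) -> int:
        addr = self.address(role)
        return s.index_of(addr.chain, addr.res_num, atom_name)

    @property
    def protein_chain(self) -> str:
        return self.steric_gate.chain

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            role: {"chain": self.address(role).chain, "res_num": self.address(role).res_num}
            for role in PROTEIN_ROLES + ("nucleotide", "template_base")
        }
        d["nucleotide"]["code"] = self.nucleotide_code
        d["nucleotide"]["sugar"] = self.sugar
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SiteMap":
        kw = {}
        for role in PROTEIN_ROLES + ("nucleotide", "template_base"):
            entry = d[role]
            kw[role] = SiteAddress(str(entry["chain"]), int(entry["res_num"]))
        return cls(
            nucleotide_code=str(d["nucleotide"].get("code", "UTP")),
            sugar=str(d["nucleotide"].get("sugar", "ribo")),
            **kw,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SiteMap":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def default_site_map(chain: str = "A", nucleotide_chain: str = "N",
                     template_chain: str = "T", sugar: str = "ribo",
                     nucleotide_code: str | None = None) -> SiteMap:
    """The Pol2-core numbering: Y645 gate, N828 sensor, D877/D640 catalytic,
    M644 neighbour, Y831 stack; nucleotide and template on their own chains."""
    if nucleotide_code is None:
        nucleotide_code = "UTP" if sugar == "ribo" else "TTP"
    return SiteMap(
        steric_gate=SiteAddress(chain, 645),
        sensor=SiteAddress(chain, 828),
        catalytic_1=SiteAddress(chain, 877),
        catalytic_2=SiteAddress(chain, 640),
        neighbor=SiteAddress(chain, 644),
        stack=SiteAddress(chain, 831),
        nucleotide=SiteAddress(nucleotide_chain, 1),
        template_base=SiteAddress(template_chain, 1),
        nucleotide_code=nucleotide_code,
        sugar=sugar,
    )
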