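"""Fixed-column PDB coordinate I/O and atom selection.

This is the atom-addressing layer the geometric modules build on: parsed
records keep author residue numbering (so Y645, N828, D877 of Pol2-core are
addressed by their familiar numbers), atom names are normalized to the
prime convention (``C2*`` becomes ``C2'``), and alternate locations are
resolved by explicit policy before any geometry is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    FormatOverflowError,
    MissingAtomError,
    PdbParseError,
)

__all__ = [
    "AtomRecord",
    "Structure",
    "AtomSelector",
    "normalize_atom_name",
    "read_pdb",
    "read_pdb_single",
    "write_pdb",
    "write_pdb_models",
    "resolve_altlocs",
    "select_atoms",
]

#: Ligand-name synonyms applied after prime normalization.  Deposition
#: dialects differ (v2 primes, alternative phosphate-oxygen labels); the
#: table is deliberately small and extensible per call.
DEFAULT_NAME_SYNONYMS: dict[str, str] = {
    "O1B": "O1B",  # identity entries document the canonical spelling
    "O2B": "O2B",
}

WATER_RES_NAMES = frozenset({"HOH", "WAT", "DOD"})


def normalize_atom_name(raw: str, synonyms: dict[str, str] | None = None) -> str:
    """Strip whitespace, map PDB v2 primes (``*``) to v3 (``'``), apply synonyms."""
    name = raw.strip().replace("*", "'")
    table = DEFAULT_NAME_SYNONYMS if synonyms is None else {**DEFAULT_NAME_SYNONYMS, **synonyms}
    return table.get(name, name)


@dataclass(slots=True)
class AtomRecord:
    """One ATOM/HETATM record with normalized identity and Cartesian position (Å)."""

    serial: int
    name: str
    altloc: str
    res_name: str
    chain: str
    res_num: int
    icode: str
    pos: np.ndarray
    occupancy: float = 1.0
    element: str = ""
    is_het: bool = False

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.name:
            raise ValueError("atom name empty after normalization")

    @property
    def address(self) -> tuple[str, int, str]:
        """(chain, res_num, name) — the addressing triple used throughout."""
        return (self.chain, self.res_num, self.name)

    def moved(self, new_pos: np.ndarray) -> "AtomRecord":
        return replace(self, pos=np.asarray(new_pos, dtype=float))


@dataclass
class Structure:
    """An ordered atom list from one coordinate model."""

    atoms: list[AtomRecord]
    model_id: int = 1
    source_id: str = ""
    _index: dict[tuple[str, int, str], int] | None = field(
        default=None, repr=False, compare=False
    )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom roster")
        atoms = [a.moved(c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, self.model_id if model_id is None else model_id, self.source_id)

    def index_of(self, chain: str, res_num: int, name: str) -> int:
        if self._index is None:
            self._index = {a.address: i for i, a in enumerate(self.atoms)}
        try:
            return self._index[(chain, res_num, name)]
        except KeyError:
            raise MissingAtomError([(chain, res_num, name)]) from None

    def atom(self, chain: str, res_num: int, name: str) -> AtomRecord:
        return self.atoms[self.index_of(chain, res_num, name)]

    def has_atom(self, chain: str, res_num: int, name: str) -> bool:
        if self._index is None:
            self._index = {a.address: i for i, a in enumerate(self.atoms)}
        return (chain, res_num, name) in self._index

    def roster(self) -> list[tuple[str, int, str, str]]:
        """(chain, res_num, icode, name) per atom — identity without coordinates."""
        return [(a.chain, a.res_num, a.icode, a.name) for a in self.atoms]


@dataclass(frozen=True)
class AtomSelector:
    """Declarative atom selection; empty res_nums/atom_names mean "match any"."""

    chain: str | None = None
    res_nums: tuple[int, ...] = ()
    atom_names: tuple[str, ...] = ()
    het_policy: str = "include"  # include | exclude | only

    def __post_init__(self):
        if self.het_policy not in ("include", "exclude", "only"):
            raise ValueError(f"unknown het_policy {self.het_policy!r}")
        object.__setattr__(self, "res_nums", tuple(self.res_nums))
        object.__setattr__(
            self, "atom_names", tuple(normalize_atom_name(n) for n in self.atom_names)
        )

    def matches(self, a: AtomRecord) -> bool:
        if self.chain is not None and a.chain != self.chain:
            return False
        if self.res_nums and a.res_num not in self.res_nums:
            return False
        if self.atom_names and a.name not in self.atom_names:
            return False
        if self.het_policy == "exclude" and a.is_het:
            return False
        if self.het_policy == "only" and not a.is_het:
            return False
        return True


def _parse_record(line: str, lineno: int, is_het: bool,
                  synonyms: dict[str, str] | None) -> AtomRecord:
    # PDB v3 fixed columns (0-based slices).
    try:
        padded = line.rstrip("\n").ljust(80)
        serial = int(padded[6:11])
        name = normalize_atom_name(padded[12:16], synonyms)
        altloc = padded[16].strip()
        res_name = padded[17:20].strip()
        chain = padded[21].strip()
        res_num = int(padded[22:26])
        icode = padded[26].strip()
        pos = (float(padded[30:38]), float(padded[38:46]), float(padded[46:54]))
        occ_field = padded[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = padded[76:78].strip()
    except (ValueError, IndexError) as exc:
        raise PdbParseError(f"line {lineno}: malformed fixed-width record: {exc}") from None
    return AtomRecord(serial, name, altloc, res_name, chain, res_num, icode,
                      np.array(pos), occupancy, element, is_het)


def read_pdb(text: str | Iterable[str], source_id: str = "",
             synonyms: dict[str, str] | None = None) -> list[Structure]:
    """Parse a PDB character stream; each MODEL block yields one Structure.

    A file without MODEL records yields a single Structure.  Raises
    :class:`EmptyInputError` when no coordinate record is found and
    :class:`PdbParseError` (naming the line) on malformed records.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    structures: list[Structure] = []
    current: list[AtomRecord] = []
    model_id = 1
    in_model = False
    for lineno, line in enumerate(lines, start=1):
        tag = line[:6]
        if tag == "MODEL ":
            if current:
                structures.append(Structure(current, model_id, source_id))
                current = []
            try:
                model_id = int(line[6:].split()[0])
            except (ValueError, IndexError):
                raise PdbParseError(f"line {lineno}: malformed MODEL record") from None
            in_model = True
        elif tag == "ENDMDL":
            structures.append(Structure(current, model_id, source_id))
            current = []
            in_model = False
        elif tag in ("ATOM  ", "HETATM"):
            current.append(_parse_record(line, lineno, tag == "HETATM", synonyms))
    if current or (in_model and not structures):
        structures.append(Structure(current, model_id, source_id))

    if not any(len(s) for s in structures):
        raise EmptyInputError("no ATOM/HETATM records in input")
    return [s for s in structures if len(s)]


def read_pdb_single(text: str | Iterable[str], source_id: str = "",
                    synonyms: dict[str, str] | None = None) -> Structure:
    """Like :func:`read_pdb` but expects (and returns) exactly one model."""
    models = read_pdb(text, source_id, synonyms)
    if len(models) != 1:
        raise PdbParseError(f"expected a single model, found {len(models)}")
    return models[0]


def _format_atom_name(name: str, element: str) -> str:
    # Column 13 is reserved for two-letter element symbols; one-letter
    # elements start at column 14 unless the name already fills 4 chars.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_pdb(s: Structure, *, end: bool = True) -> str:
    """Serialize one Structure to fixed-column PDB text.

    Coordinates outside the %8.3f field raise :class:`FormatOverflowError`;
    read→write→read is the identity on all fields (coordinates at 3 decimals).
    """
    out = []
    for a in s.atoms:
        if np.any(np.abs(a.pos) >= 10000.0):
            raise FormatOverflowError(
                f"atom {a.address}: coordinate {a.pos} exceeds the %8.3f PDB column"
            )
        tag = "HETATM" if a.is_het else "ATOM  "
        out.append(
            f"{tag}{a.serial:>5} {_format_atom_name(a.name, a.element)}"
            f"{a.altloc or ' '}{a.res_name:>3} {a.chain or ' '}"
            f"{a.res_num:>4}{a.icode or ' '}   "
            f"{a.pos[0]:8.3f}{a.pos[1]:8.3f}{a.pos[2]:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2}"
        )
    if end:
        out.append("END")
    return "\n".join(out) + "\n"


def write_pdb_models(models: Sequence[Structure]) -> str:
    """Serialize several models as a MODEL/ENDMDL multi-model stream."""
    chunks = []
    for i, s in enumerate(models, start=1):
        chunks.append(f"MODEL {i:>8}")
        chunks.append(write_pdb(s, end=False).rstrip("\n"))
        chunks.append("ENDMDL")
    chunks.append("END")
    return "\n".join(chunks) + "\n"


def resolve_altlocs(s: Structure, policy: str = "highest_occupancy") -> Structure:
    """Keep at most one alternate location per (chain, res_num, icode, name).

    ``highest_occupancy`` keeps the most occupied conformer, ties broken to
    the lexicographically smallest altloc id; ``prefer_label`` keeps the
    smallest altloc id outright.  Altloc-free input is returned unchanged.
    """
    if policy not in ("highest_occupancy", "prefer_label"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    if not any(a.altloc for a in s.atoms):
        return s

    best: dict[tuple, tuple] = {}  # key -> (sort_key, first_seen_order, atom)
    order: list[tuple] = []
    for i, a in enumerate(s.atoms):
        key = (a.chain, a.res_num, a.icode, a.name)
        if policy == "highest_occupancy":
            rank = (-a.occupancy, a.altloc)
        else:
            rank = (a.altloc,)
        if key not in best:
            best[key] = (rank, i, a)
            order.append(key)
        elif rank < best[key][0]:
            best[key] = (rank, best[key][1], a)
    atoms = [replace(best[k][2], altloc="") for k in order]
    return Structure(atoms, s.model_id, s.source_id)


def select_atoms(s: Structure, sel: AtomSelector) -> list[AtomRecord]:
    """Resolve a selector to an ordered atom list.

    With explicit res_nums and atom_names the result follows the listed
    (res_num, atom_name) order and every requested combination must exist;
    absences are collected and raised together as :class:`MissingAtomError`.
    Wildcard selectors return matches in structure order.
    """
    if sel.res_nums and sel.atom_names:
        picked: list[AtomRecord] = []
        missing: list[tuple] = []
        by_addr: dict[tuple, AtomRecord] = {}
        for a in s.atoms:
            if sel.matches(a):
                by_addr.setdefault((a.res_num, a.name), a)
        for rn in sel.res_nums:
            for name in sel.atom_names:
                a = by_addr.get((rn, name))
                if a is None:
                    missing.append((sel.chain or "*", rn, name))
                else:
                    picked.append(a)
        if missing:
            raise MissingAtomError(missing)
        return picked

    picked = [a for a in s.atoms if sel.matches(a)]
    if sel.res_nums:
        found = {a.res_num for a in picked}
        missing = [(sel.chain or "*", rn, "*") for rn in sel.res_nums if rn not in found]
        if missing:
            raise MissingAtomError(missing)
        picked.sort(key=lambda a: sel.res_nums.index(a.res_num))
    return picked
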