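"""Least-squares rigid superposition (Kabsch) with the named alignment presets.

Three residue sets recur in comparisons of Pol2-core depositions and are kept
as presets:

* ``finger_palm`` — Cα of finger residues 828, 831, 833 plus palm residue 645;
  superimposes the incoming dNTPs essentially perfectly.
* ``palm`` — Cα of palm residues 877, 640, 556, 645 plus finger residue 836.
* ``palm_b`` — Cα of palm residues 640, 644, 645, 556 plus finger residue 836.

All fits are unweighted and reflections are excluded by construction:
biological coordinates must never be mirrored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, MissingAtomError
from .sitemap import SiteMap
from .structure_io import Structure

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "AlignmentScheme",
    "SCHEMES",
    "get_scheme",
    "kabsch_fit",
    "apply_transform",
    "align_structures",
]


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R·x + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is not proper (det != +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    scheme: str = "custom"


@dataclass(frozen=True)
class AlignmentScheme:
    """Named ordered list of (res_num, atom_name) pairs to fit on."""

    name: str
    atoms: tuple[tuple[int, str], ...]


SCHEMES: dict[str, AlignmentScheme] = {
    "finger_palm": AlignmentScheme(
        "finger_palm", tuple((r, "CA") for r in (828, 831, 833, 645))),
    "palm": AlignmentScheme(
        "palm", tuple((r, "CA") for r in (877, 640, 556, 645, 836))),
    "palm_b": AlignmentScheme(
        "palm_b", tuple((r, "CA") for r in (640, 644, 645, 556, 836))),
}


def get_scheme(scheme: str | AlignmentScheme) -> AlignmentScheme:
    if isinstance(scheme, AlignmentScheme):
        return scheme
    try:
        return SCHEMES[scheme]
    except KeyError:
        raise KeyError(
            f"unknown alignment scheme {scheme!r}; presets: {sorted(SCHEMES)}"
        ) from None


def _check_not_collinear(pts: np.ndarray) -> None:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; rotation underdetermined")


def kabsch_fit(ref: Sequence, mov: Sequence, scheme: str = "custom") -> SuperpositionResult:
    """Optimal proper rigid transform taking ``mov`` onto ``ref``.

    Minimizes the RMSD over all rotations with det +1 plus translations
    (Kabsch).  Requires ≥3 non-collinear matched points.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError(f"point count mismatch: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 matched 3D points")
    _check_not_collinear(ref)
    _check_not_collinear(mov)

    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mov - mov_c)
    R = rot.as_matrix()
    t = ref_c - R @ mov_c
    fitted = mov @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(RigidTransform(R, t), rmsd, ref.shape[0], scheme)


def apply_transform(t: RigidTransform, coords: Sequence) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    single = coords.ndim == 1
    out = np.atleast_2d(coords) @ t.rotation.T + t.translation
    return out[0] if single else out


def _scheme_coords(s: Structure, scheme: AlignmentScheme, site: SiteMap | None) -> np.ndarray:
    chain = site.protein_chain if site is not None else None
    missing, rows = [], []
    for res_num, name in scheme.atoms:
        if chain is None:
            hits = [a for a in s.atoms if a.res_num == res_num and a.name == name]
            if not hits:
                missing.append(("*", res_num, name))
            else:
                rows.append(hits[0].pos)
        else:
            if s.has_atom(chain, res_num, name):
                rows.append(s.atom(chain, res_num, name).pos)
            else:
                missing.append((chain, res_num, name))
    if missing:
        raise MissingAtomError(missing)
    return np.array(rows)


def align_structures(ref: Structure, mov: Structure, scheme: str | AlignmentScheme,
                     site_ref: SiteMap | None = None,
                     site_mov: SiteMap | None = None,
                     ) -> tuple[Structure, SuperpositionResult]:
    """Superimpose ``mov`` onto ``ref`` on a scheme's atoms; returns the fully
    transformed copy of ``mov`` plus the fit result."""
    sch = get_scheme(scheme)
    ref_pts = _scheme_coords(ref, sch, site_ref)
    mov_pts = _scheme_coords(mov, sch, site_mov)
    result = kabsch_fit(ref_pts, mov_pts, scheme=sch.name)
    moved = mov.with_coords(apply_transform(result.transform, mov.coords))
    return moved, result
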