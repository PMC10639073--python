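"""Exception hierarchy shared across the package."""


class PolsensorError(Exception):
    """Base class for all package-specific errors."""


class PdbParseError(PolsensorError):
    """A fixed-column PDB record could not be parsed; message names the line."""


class EmptyInputError(PolsensorError):
    """Input stream contained no ATOM/HETATM records."""


class FormatOverflowError(PolsensorError):
    """A coordinate does not fit the %8.3f PDB column."""


class MissingAtomError(PolsensorError):
    """One or more requested atoms are absent from the structure."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "missing atoms: " + ", ".join(str(m) for m in self.missing)
        )


class DegenerateGeometryError(PolsensorError):
    """Point set too small or collinear for a rigid fit."""


class UnsupportedResidueError(PolsensorError):
    """A residue lacks the atom a descriptor is defined on."""


class ChemistryTableError(PolsensorError):
    """No donor-antecedent entry for the addressed atom."""


class CriteriaConfigError(PolsensorError):
    """Relaxed H-bond criteria do not dominate strict criteria."""


class InconsistentTrajectoryError(PolsensorError):
    """Frames of a trajectory disagree on the atom roster."""


class ConstructionError(PolsensorError):
    """A synthetic fixture request is geometrically unrealizable."""


class ConfigError(PolsensorError):
    """An analysis configuration is invalid."""
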