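"""Exception hierarchy for pdzdesign."""


class PdzDesignError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PdzDesignError, ValueError):
    """A generator or run configuration violates its invariants."""


class PdbParseError(PdzDesignError, ValueError):
    """A PDB file could not be interpreted as a single-chain scaffold."""


class MissingAtomError(PdbParseError):
    """A residue lacks one of the required backbone atoms."""


class DegenerateGeometryError(PdzDesignError, ValueError):
    """Coordinates coincide where a finite distance is required."""


class UnsupportedModeError(PdzDesignError, ValueError):
    """An operation was requested in a solvation mode it does not support."""


class NoMovesError(PdzDesignError, ValueError):
    """The design spec leaves no position free to move."""


class FitError(PdzDesignError, RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
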