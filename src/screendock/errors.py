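"""Exception hierarchy for the screening pipeline.

All package-specific failures derive from :class:`ScreendockError` so a
screen driver can catch one base class, record the job as failed, and keep
dispatching.
"""


class ScreendockError(Exception):
    """Base class for all screendock failures."""


class StructuralParseError(ScreendockError):
    """A file's block structure is malformed (e.g. unbalanced BRANCH nesting).

    Carries the 1-based line number where the problem was detected.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class FieldParseError(ScreendockError):
    """A single field failed to parse (non-numeric charge, bad count value)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class RangeError(ScreendockError):
    """A parsed value is outside its permitted range."""


class HeaderError(ScreendockError):
    """A grid-map header is invalid (odd or unequal NELEMENTS, missing keys)."""


class TruncatedMapError(ScreendockError):
    """A grid-map file holds the wrong number of lattice values."""

    def __init__(self, expected: int, found: int):
        self.expected = expected
        self.found = found
        super().__init__(
            f"grid map value count mismatch: expected {expected}, found {found}"
        )


class MissingMapError(ScreendockError):
    """A required grid map could not be located or read.

    This is the canonical per-docking failure trigger: the scheduler
    records the job as failed with the offending atom type and moves on.
    """

    def __init__(self, atom_type: str, detail: str = ""):
        self.atom_type = atom_type
        msg = f"missing grid map for atom type {atom_type!r}"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class StateMismatchError(ScreendockError):
    """A genome state is incompatible with the ligand (torsion count)."""


class IncompleteResultError(ScreendockError):
    """A docking result lacks the buffered log of one or more runs."""


class ParameterError(ScreendockError):
    """Docking parameters violate their invariants (e.g. zero population)."""


class JobTimeoutError(ScreendockError):
    """A docking exceeded the configured per-job wall-clock budget."""
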