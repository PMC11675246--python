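"""Exception hierarchy shared across the pipeline stages."""


class F8LandscapeError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(F8LandscapeError, ValueError):
    """A synthetic-data specification violates its own invariants."""


class MissingReferenceError(F8LandscapeError, KeyError):
    """The designated reference species is absent from an alignment."""


class EmptyInputError(F8LandscapeError, ValueError):
    """An operation that requires at least one record received none."""


class ConflictError(F8LandscapeError, ValueError):
    """Contradictory records (e.g. different reference residues at one position)."""


class CoverageError(F8LandscapeError, KeyError):
    """A variant position is not covered by the conservation profile."""


class UnknownToolError(F8LandscapeError, KeyError):
    """A prediction-tool name has no registered normalization map."""


class DegenerateStructureError(F8LandscapeError, ValueError):
    """Coordinates too degenerate for a rigid-body superposition."""


class LabelError(F8LandscapeError, KeyError):
    """A residue label is absent from the matrix / coordinate set."""


class BookkeepingError(F8LandscapeError, ValueError):
    """Frame-count arithmetic does not divide evenly."""


class FixtureError(F8LandscapeError, RuntimeError):
    """A packaged fixture failed its integrity check."""


class StageError(F8LandscapeError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
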