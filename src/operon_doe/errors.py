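"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`OperonDoeError` so
callers (and the CLI) can distinguish validation problems from bugs.
"""


class OperonDoeError(Exception):
    """Base class for all operon-doe errors."""


class SchemaError(OperonDoeError):
    """An input table is missing a required column or is malformed."""


class PartValidationError(OperonDoeError):
    """A part row violates a field invariant (duplicate id, bad sequence...)."""


class EmptyLibraryError(OperonDoeError):
    """A part file contained no data rows."""


class UnrankedPartError(OperonDoeError):
    """An operation required ranks that have not been assigned."""


class DesignSpaceError(OperonDoeError):
    """The factor structure cannot be built from the given library/config."""


class DegenerateTermError(OperonDoeError):
    """A model term refers to a factor with a single level."""


class InfeasibleDesignError(OperonDoeError):
    """Requested run count is smaller than the model column count."""


class SingularDesignError(OperonDoeError):
    """No nonsingular starting design could be drawn."""


class StitchCollisionError(OperonDoeError):
    """Pre-existing stitch IDs conflict with the IDs being assigned."""


class LayoutError(OperonDoeError):
    """A part or reagent required by a construct is absent from the source plates."""


class CapacityError(OperonDoeError):
    """A destination well (or plate) would exceed its capacity."""


class UnderdeterminedError(OperonDoeError):
    """Too few distinct points to fit the requested curve."""


class UndefinedTitreError(OperonDoeError):
    """A titre is requested for a sample with zero dry cell weight but signal."""


class AliasingError(OperonDoeError):
    """The observed model matrix is rank deficient (confounded terms)."""


class InfeasibleFitError(OperonDoeError):
    """Fewer usable observations than model parameters."""


class PipelineError(OperonDoeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
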