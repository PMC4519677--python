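"""Exception hierarchy shared across the package.

Every named failure mode of the pipeline raises a subclass of
:class:`BarcodeKitError`, so callers can catch one type at the CLI boundary.
"""


class BarcodeKitError(Exception):
    """Base class for all package-specific errors."""


class SequenceFormatError(BarcodeKitError):
    """Malformed or empty sequence input."""


class DuplicateIdError(SequenceFormatError):
    """The same record identifier appears more than once."""


class IllegalCharacterError(SequenceFormatError):
    """A sequence contains a character outside the accepted alphabet."""


class LengthMismatchError(SequenceFormatError):
    """Paired records (sequence/quality, alignment rows) disagree in length."""


class SpeciesMapError(BarcodeKitError):
    """Problems with the sample-to-species table or an unlabeled sample."""


class AlignmentError(BarcodeKitError):
    """Invalid input to the aligner or a ragged ingested alignment."""


class SaturationError(BarcodeKitError):
    """A distance correction is undefined (log argument <= 0)."""


class UndefinedDistanceError(BarcodeKitError):
    """A pair shares no comparable sites, or a saturated pair in strict mode."""


class TreeError(BarcodeKitError):
    """Invalid input to tree reconstruction."""


class DesignError(BarcodeKitError):
    """Primer design preconditions violated (e.g. ambiguous bases in a primer)."""


class SimulationError(BarcodeKitError):
    """Simulation parameters are infeasible."""


class PipelineError(BarcodeKitError):
    """A pipeline stage failed; carries the stage name and cause."""
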