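"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`AmpharmError` so that the pipeline
driver can abort with the stage name and the offending record.
"""


class AmpharmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AmpharmError, ValueError):
    """A configuration object violates one of its invariants.

    The message names the offending field.
    """


class InputError(AmpharmError, ValueError):
    """Raw input data do not satisfy the preconditions of an operation."""


class DegenerateDataError(AmpharmError, ValueError):
    """Data carry no information for the requested fit (e.g. all responses equal)."""


class DegenerateNormalizationError(AmpharmError, ValueError):
    """The reference (WT) curve has a non-positive span."""


class AlignmentError(AmpharmError, ValueError):
    """Concentration grids of experiments to be combined do not match."""


class PairingError(AmpharmError, ValueError):
    """WT and mutant records cannot be paired (receptor or replication mismatch)."""


class UnknownConstructError(AmpharmError, KeyError):
    """A construct id is not present in the packaged reference tables."""
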