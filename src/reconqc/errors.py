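"""Exception hierarchy for reconqc.

All errors raised deliberately by the package derive from :class:`ReconQCError`
so callers can catch the package's failures with a single except clause.
"""


class ReconQCError(Exception):
    """Base class for all reconqc errors."""


class ValidationError(ReconQCError):
    """An input violates a documented precondition (shape, sign, identity)."""


class PairingError(ReconQCError):
    """Slice pairing between the two arms of an exam produced no matches."""


class UndefinedMetricError(ReconQCError):
    """A metric is mathematically undefined for the given input.

    Examples: pSNR with an all-zero reference, SAM with a zero-norm vector,
    VIF with a constant (zero-information) reference.
    """


class DegenerateInputError(ReconQCError):
    """The input is degenerate for the requested operation (e.g. a constant
    image for BRISQUE, whose local contrast normalisation divides by the
    local signal deviation)."""


class InsufficientBaselineError(ReconQCError):
    """Fewer than two reference exams were available to build a baseline."""


class DegenerateBaselineError(ReconQCError):
    """A baseline has zero spread, so control limits collapse to a point."""


class ConfigError(ReconQCError):
    """A run configuration is invalid or an expected file is missing."""
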