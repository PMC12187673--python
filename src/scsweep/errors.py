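"""Exception types shared across the pipeline.

All inherit from :class:`ScsweepError` so callers can catch any pipeline
failure with one clause; the sweep driver catches them per record and tags
the record instead of aborting.
"""


class ScsweepError(ValueError):
    """Base class for all scsweep errors."""


class InvalidSpecError(ScsweepError):
    """A generative or sweep specification violates its invariants."""


class InvalidInputError(ScsweepError):
    """An operation received structurally invalid input."""


class DegenerateInputError(ScsweepError):
    """Input is structurally valid but degenerate (e.g. all-zero cell)."""


class DegenerateClusterError(ScsweepError):
    """A cluster has zero scatter/diameter where an index needs it positive."""


class DegeneratePartitionError(ScsweepError):
    """The partition itself makes an index undefined (e.g. all singletons)."""


class RankDeficiencyError(ScsweepError):
    """A matrix is rank-deficient for the requested decomposition/fit."""
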