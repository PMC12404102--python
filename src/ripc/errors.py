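"""Exception hierarchy for the ripc pipeline.

Every stage raises a subclass of :class:`RIPCError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class RIPCError(Exception):
    """Base class for all ripc errors."""


class InvalidSpecError(RIPCError):
    """A phantom specification is degenerate (empty grid, empty RI interval...)."""


class EmptyForegroundError(RIPCError):
    """A foreground mask selects no voxels."""


class InsufficientPointsError(RIPCError):
    """More points were requested than the cloud contains (sampling is
    without replacement)."""


class InvalidConfigError(RIPCError):
    """A sampler / network / run configuration violates its invariants."""


class EmptyIntervalError(RIPCError):
    """The targeted RI band contains no points."""


class ShapeError(RIPCError):
    """An array has the wrong cardinality or channel count for the network."""


class InvalidDatasetError(RIPCError):
    """A labelled dataset is unusable (empty class, fewer than two classes...)."""
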