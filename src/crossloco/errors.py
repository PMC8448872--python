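"""Exception hierarchy shared across the package."""


class CrossLocoError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CrossLocoError, ValueError):
    """Input data violates a precondition (lengths, ordering, ranges)."""


class InvalidConfigError(CrossLocoError, ValueError):
    """Configuration values are inconsistent or out of range."""


class DegenerateSeriesError(CrossLocoError, ValueError):
    """A series has zero variance and cannot be normalized."""


class InsufficientGaitError(CrossLocoError, ValueError):
    """Too few foot-contact events to form stride intervals."""


class InvalidDatasetError(CrossLocoError, ValueError):
    """A training set is missing a class or a domain."""


class DegenerateLabelsError(CrossLocoError, ValueError):
    """Only one label value present where two are required."""


class NoEventsError(CrossLocoError, ValueError):
    """No qualifying events (e.g. turns) found in a trajectory."""


class DegenerateSampleError(CrossLocoError, ValueError):
    """A sample has zero variance where a test requires spread."""


class InsufficientSampleError(CrossLocoError, ValueError):
    """Too few observations for the requested statistic."""
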