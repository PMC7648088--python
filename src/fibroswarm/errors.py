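"""Exception hierarchy shared across the package."""


class FibroswarmError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(FibroswarmError, ValueError):
    """A configuration object violates its invariants."""


class InputError(FibroswarmError, ValueError):
    """An input (image, table, ROI) violates the operation's contract."""


class ValidationError(InputError):
    """A file or table failed structural validation on read."""


class PlacementError(FibroswarmError, RuntimeError):
    """Synthetic objects could not be placed without overlap."""


class InvalidFlowError(InvalidConfigError):
    """A flow specification is incomplete or displaces outside the image."""


class UndefinedMetricError(FibroswarmError, ValueError):
    """The requested statistic is undefined on this input (e.g. empty foreground)."""


class PlanError(FibroswarmError, ValueError):
    """A pipeline stage's dependencies are not satisfied by the run plan."""
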