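"""Exception types shared across the package."""


class VmapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VmapError, ValueError):
    """A configuration object violates its invariants (geometry, ranges, ...)."""


class InputError(VmapError, ValueError):
    """An input array or value violates an operation's precondition."""


class DatasetError(VmapError):
    """On-disk dataset is incomplete or inconsistent with its manifest."""


class LabelingError(VmapError):
    """A map cannot be assigned a category (e.g. missing follow-up)."""


class UndefinedMetricError(VmapError):
    """A metric is undefined for the given data (empty class, no events)."""


class ThresholdError(VmapError):
    """Risk dichotomization is degenerate (e.g. all scores identical)."""


class TrainingError(VmapError):
    """Training diverged (non-finite loss)."""
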