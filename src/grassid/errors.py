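"""Exception hierarchy for dataset and pipeline contract violations."""


class GrassidError(ValueError):
    """Base class for all validation and contract errors."""


class ConfigError(GrassidError):
    """An invalid configuration value; the message names the offending field."""


class CompletenessError(GrassidError):
    """An observation is missing one or more required perspectives."""


class DimensionError(GrassidError):
    """Feature vectors do not share a single dimension."""


class DuplicateError(GrassidError):
    """Duplicate observation id or duplicate (obs_id, perspective) pair."""


class StratificationError(GrassidError):
    """A species' observation count does not match the requested split sizes."""


class AlignmentError(GrassidError):
    """Score matrices or prediction/truth maps do not share keys or ordering."""


class MissingPerspectiveError(GrassidError):
    """A fusion subset references a perspective with no score matrix."""


class TrainingError(GrassidError):
    """The training set violates a classifier precondition."""


class DegenerateInputError(GrassidError):
    """An input is formally valid but carries no usable signal (e.g. all-zero accuracies)."""
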