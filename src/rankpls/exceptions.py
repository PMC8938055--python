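"""Exception and warning types shared across the package."""


class RankPLSError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RankPLSError, ValueError):
    """Malformed data passed to an operation (length mismatch, too few rows, ...)."""


class ConfigError(RankPLSError, ValueError):
    """Invalid configuration (unknown measure name, impossible component count, ...)."""


class FormatError(RankPLSError, ValueError):
    """A file on disk does not conform to the expected tabular layout."""


class FitError(RankPLSError, RuntimeError):
    """Model fitting could not proceed (degenerate response, all-zero weights, ...)."""


class EmptySelectionError(RankPLSError, RuntimeError):
    """A variable-selection step retained no predictors."""


class SplitError(RankPLSError, RuntimeError):
    """A stratified train/test split could not be drawn."""


class DegenerateInputWarning(UserWarning):
    """An association measure hit a degenerate input (constant vector, fully tied
    variable, zero entropy) and returned 0 by convention."""
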