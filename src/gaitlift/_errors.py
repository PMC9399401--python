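"""Exception hierarchy.

Config errors, data/format errors, and degenerate-result errors are kept
distinct so the CLI can map them to distinct exit codes.
"""


class GaitliftError(Exception):
    """Base class for all package errors."""


class ConfigError(GaitliftError):
    """Invalid configuration value."""


class FormatError(GaitliftError):
    """Malformed input file (bad JSON, wrong joint count, bad header)."""


class SchemaError(FormatError):
    """Input does not match the declared keypoint/marker schema."""


class DataError(GaitliftError):
    """Input parses but violates a precondition (NaNs, too short, misaligned)."""


class DegenerateError(GaitliftError):
    """A geometric or statistical quantity is undefined on this input."""


class UnrecoverableJointError(DataError):
    """A joint is missing in every frame and cannot be gap-filled."""


class DivergenceError(GaitliftError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite training loss at epoch {epoch}")


class NoCycleError(DataError):
    """Fewer than two heel strikes: no gait cycle can be formed."""


class UndefinedEntropyError(DegenerateError):
    """Sample entropy undefined (no template matches at length m)."""


class ZeroVarianceError(DegenerateError):
    """Constant series cannot be standardized."""
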