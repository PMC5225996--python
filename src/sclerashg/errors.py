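"""Exception hierarchy for sclerashg."""


class SclerashgError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(SclerashgError, ValueError):
    """A parameter violates its documented precondition."""


class UnsupportedImageError(SclerashgError, ValueError):
    """The file is not a single-plane integer grayscale TIFF."""


class ImageReadError(SclerashgError, IOError):
    """The image file could not be read (missing, truncated, corrupt)."""


class FiberPlacementError(SclerashgError, RuntimeError):
    """Non-overlapping fiber placement failed within the rejection budget."""


class SeedNotOnFiberError(SclerashgError, ValueError):
    """The tracing seed point does not sit on a bright ridge."""


class TraceFailedError(SclerashgError, RuntimeError):
    """Ridge following produced a degenerate (<2 point) trace."""


class DegenerateFiberError(SclerashgError, ValueError):
    """Chord length too small for the arc/chord ratio to be meaningful."""


class DegenerateTestError(SclerashgError, ValueError):
    """A significance test is undefined (zero variance with nonzero effect)."""


class UndefinedStatisticError(SclerashgError, ValueError):
    """The Waviness-%% denominator vanishes (control fibers perfectly straight)."""
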