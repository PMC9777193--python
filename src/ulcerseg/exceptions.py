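"""Exception hierarchy for the segmentation pipeline."""


class UlcerSegError(Exception):
    """Base class for all package-specific errors."""


class ShapeMismatchError(UlcerSegError, ValueError):
    """Two arrays that must be pixel-aligned have different shapes."""


class EmptyMaskError(UlcerSegError, ValueError):
    """A mask that must contain foreground pixels is empty."""


class InsufficientEdgeError(UlcerSegError, ValueError):
    """Too few edge pixels to attempt shape recognition."""


class BorderNotFoundError(UlcerSegError, RuntimeError):
    """The accumulator peak fell below the minimum vote fraction."""


class CorneaError(UlcerSegError, ValueError):
    """The cornea disk is degenerate or outside the image."""


class ConfigError(UlcerSegError, ValueError):
    """Invalid or unknown configuration keys/values."""


class StageError(UlcerSegError, RuntimeError):
    """A pipeline stage failed; carries the stage name.

    ``__cause__`` holds the underlying error.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
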