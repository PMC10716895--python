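"""Exception hierarchy shared across the package."""


class LigscreenError(Exception):
    """Base class for all package errors."""


class FormatError(LigscreenError):
    """A structure or trajectory file does not parse under its dialect."""


class EmptyStructureError(FormatError):
    """A structure file contained no atoms."""


class TrajectoryAlignmentError(LigscreenError):
    """A trajectory frame's atom count does not match its system."""

    def __init__(self, frame_index: int, expected: int, found: int):
        self.frame_index = frame_index
        super().__init__(
            f"frame {frame_index}: expected {expected} atoms, found {found}"
        )


class ParameterError(LigscreenError):
    """A required per-atom or bonded parameter is missing or invalid."""
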