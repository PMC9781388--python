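"""Exception hierarchy shared across the pipeline stages."""


class DentextureError(Exception):
    """Base class for all package errors."""


class ParameterError(DentextureError, ValueError):
    """An argument violates an operation's contract."""


class NoForegroundError(DentextureError):
    """Segmentation found no foreground region to crop."""


class StageError(DentextureError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
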