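"""Exception hierarchy for the tgmo package."""


class TgmoError(Exception):
    """Base class for all tgmo errors."""


class DesignError(TgmoError):
    """Invalid or unsupported experimental design request."""


class FitError(TgmoError):
    """Model fitting failed or was called with inconsistent inputs."""


class DoseError(TgmoError):
    """Dose-response or dose-selection failure."""


class SelectionError(TgmoError):
    """Drug elimination / combination selection failure."""


class PipelineError(TgmoError):
    """A pipeline stage failed; the message names the stage."""
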