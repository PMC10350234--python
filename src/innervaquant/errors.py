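"""Exception hierarchy shared by all pipeline stages."""


class InnervaquantError(Exception):
    """Base class for all package errors."""


class ValidationError(InnervaquantError):
    """An input violates a documented precondition or invariant."""


class ConfigurationError(InnervaquantError):
    """A requested option (channel name, denoiser, label) does not exist."""


class GenerationError(InnervaquantError):
    """The synthetic generator cannot satisfy the requested parameters."""


class ZeroAreaError(ValidationError):
    """A (region, layer) selection contains no pixels; density is undefined."""


class TrainingDivergenceError(InnervaquantError):
    """Denoiser training produced a non-finite loss."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(f"non-finite training loss {loss!r} at epoch {epoch}")
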