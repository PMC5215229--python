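"""Exception hierarchy for the apri package."""


class APRIError(Exception):
    """Base class for all apri-specific errors."""


class FormatError(APRIError):
    """A file does not conform to the expected on-disk layout (e.g. ragged rows)."""


class ValidationError(APRIError):
    """Input data violates a contract (non-numeric cells, non-finite values, bad shapes)."""


class NumericalError(APRIError):
    """A numerical routine failed (singular system, eigensolver breakdown)."""
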