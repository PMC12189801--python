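"""Exception hierarchy for the accca pipeline."""


class AcccaError(Exception):
    """Base class for all accca errors."""


class InputError(AcccaError, ValueError):
    """Invalid input data (non-finite pixels, wrong shape, out-of-range values)."""


class ConfigError(AcccaError, ValueError):
    """Invalid parameter combination (bad kernel radius, CFL violation, ...)."""


class NoTissueError(AcccaError):
    """No pixel exceeded the optical-density transparency threshold."""


class DegenerateStainError(AcccaError):
    """The tissue OD cloud does not span a plane; stain vectors cannot be estimated."""
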