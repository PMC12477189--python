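"""Exception hierarchy shared across the package."""


class PhenoboxError(Exception):
    """Base class for all package-specific errors."""


class LabelParseError(PhenoboxError):
    """A label-file line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class UnknownClassError(PhenoboxError):
    """A class id absent from the configured class map."""


class DegenerateBoxError(PhenoboxError):
    """A box with zero width or height where a proper box is required."""


class MissingCalibrationError(PhenoboxError):
    """No calibration-board box available for scale conversion."""


class MissingTraitError(PhenoboxError):
    """A required trait class (e.g. the stem/height box) is absent."""


class ConfigError(PhenoboxError):
    """Invalid configuration value (ratios, weights, noise levels...)."""


class SceneFitError(PhenoboxError):
    """A sampled plant could not be placed inside the image frame."""
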