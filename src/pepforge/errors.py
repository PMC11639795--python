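"""Exception hierarchy shared across the package."""


class PepforgeError(Exception):
    """Base class for all package-specific errors."""


class EmptyStructureError(PepforgeError):
    """Raised when an operation receives a structure with no usable atoms."""


class SelectionError(PepforgeError):
    """Raised when a chain/residue selection cannot be satisfied."""


class ConfigError(PepforgeError):
    """Raised for unknown parameter-set names or invalid configuration."""


class SequenceError(PepforgeError):
    """Raised for sequences containing non-standard residue letters, or
    sequences too short for the requested encoding."""


class DataError(PepforgeError):
    """Raised when a dataset is too small or otherwise unusable."""


class FormatError(PepforgeError):
    """Raised when a text table is missing required columns."""


class PipelineError(PepforgeError):
    """Raised when a pipeline stage fails; names the failing stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
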