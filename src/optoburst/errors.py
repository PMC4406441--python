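"""Package-level exception types."""


class OptoburstError(Exception):
    """Base class for all package errors."""


class ParameterError(OptoburstError, ValueError):
    """An argument is outside its admissible range."""


class ProtocolError(OptoburstError, ValueError):
    """A stimulation protocol is inconsistent with the recording/simulation."""


class FormatError(OptoburstError, ValueError):
    """A file does not match the documented on-disk format."""


class EmptyDataError(OptoburstError, ValueError):
    """An operation received no usable (unmasked) data."""


class IncompleteDeviceError(OptoburstError, ValueError):
    """A device report is missing one measured direction."""


class InsufficientDataError(OptoburstError, ValueError):
    """Too few observations for the requested statistic."""
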