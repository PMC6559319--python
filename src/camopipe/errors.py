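"""Exception hierarchy.

``ConfigurationError`` maps to CLI exit code 2, ``DataError`` (and any other
``CamopipeError``) to exit code 1.
"""


class CamopipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CamopipeError):
    """Invalid parameters, unknown presets, malformed configs."""


class DataError(CamopipeError):
    """Invalid input data (empty masks, inverted standards, bad catches)."""


class CalibrationError(DataError):
    """Grey-standard calibration cannot be performed; names the channel."""
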