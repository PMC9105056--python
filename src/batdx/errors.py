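"""Exception hierarchy for the BAT analysis pipeline.

Validation problems (bad config, malformed input tables) map to CLI exit
code 1; anything else escaping a stage maps to exit code 2.
"""


class BatDxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BatDxError):
    """A simulation or pipeline configuration field is invalid."""


class SchemaError(BatDxError):
    """An input table is missing a required column."""


class ValidationError(BatDxError):
    """A row-level value is out of range; message carries the line number."""


class InputError(BatDxError):
    """An operation precondition is violated (too few points, empty group...)."""


class UndefinedValueError(BatDxError):
    """A derived quantity is requested where it is not defined
    (e.g. CD-sens for a basophil nonresponder)."""
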