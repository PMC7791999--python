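"""Exception hierarchy.

``FormatError`` means the file does not conform to its declared layout;
``ValidationError`` means the file parsed but the values violate an invariant;
``ParameterError`` means a caller-supplied setting is out of range.
"""


class ScreqtlError(Exception):
    """Base class for all package errors."""


class FormatError(ScreqtlError):
    """A file's structure does not match the declared format."""


class ValidationError(ScreqtlError):
    """Parsed values violate a domain invariant."""


class ParameterError(ScreqtlError):
    """A configuration value is outside its documented range."""
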