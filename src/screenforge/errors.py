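"""Exception types shared across the package."""


class ScreenforgeError(Exception):
    """Base class for all package errors."""


class FormatError(ScreenforgeError):
    """An input file does not conform to the expected layout."""


class ValidationError(ScreenforgeError):
    """An input parses but violates a documented invariant."""
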