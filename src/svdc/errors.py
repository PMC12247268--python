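"""Exception hierarchy shared across the package."""


class SvdcError(Exception):
    """Base class for all svdc-specific errors."""


class FormatError(SvdcError, ValueError):
    """A file does not conform to the expected on-disk format."""


class UnsupportedFormatError(FormatError):
    """The file is recognisable but uses a feature this package does not support."""


class ParseError(SvdcError, ValueError):
    """A value inside an otherwise well-formed file/string could not be parsed."""


class ParameterError(SvdcError, ValueError):
    """An argument is outside its documented range."""
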