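"""Exception hierarchy shared across the package."""


class PigmentScreenError(Exception):
    """Base class for all errors raised by pigmentscreen."""


class ConfigurationError(PigmentScreenError):
    """Invalid layout, generator spec, or run configuration."""


class ParseError(PigmentScreenError):
    """Malformed input file; message cites file and line where possible."""


class DataError(PigmentScreenError):
    """Well data that cannot be analysed (missing controls, degenerate plate,
    insufficient points)."""


class NumericalError(PigmentScreenError):
    """A numerical routine failed (no bracket for a root, non-finite fit)."""
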