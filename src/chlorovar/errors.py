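"""Exception types shared across the pipeline."""


class ChlorovarError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ChlorovarError):
    """A file could not be parsed; the message names the offending row."""


class ValidationError(ChlorovarError):
    """Input data violate an invariant (monotone time, value ranges, ...)."""
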