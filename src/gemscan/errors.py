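"""Exception hierarchy shared across the tool suite."""


class GemscanError(Exception):
    """Base class for all gemscan errors."""


class ParseError(GemscanError):
    """Malformed input file (ragged rows, non-numeric fields, ...)."""


class ValidationError(GemscanError):
    """Well-formed input that violates a domain contract."""


class DegeneracyError(GemscanError):
    """A model is unidentifiable for the given inputs (zero residual
    variance, collinear interaction product, ...)."""
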