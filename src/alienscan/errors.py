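"""Exception hierarchy shared across the package."""


class AlienscanError(Exception):
    """Base class for all errors raised by alienscan."""


class ValidationError(AlienscanError):
    """Malformed or inconsistent input data."""


class ParameterError(AlienscanError):
    """A parameter value outside its admissible range."""


class UnencodableError(AlienscanError):
    """A sequence cannot be encoded under the requested feature set."""


class DatasetTooSmallError(ValidationError):
    """Fewer encodable genes than the analysis requires (minimum 4)."""


class DegenerateFitError(AlienscanError):
    """The one-class SVM could not produce a usable decision function."""
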