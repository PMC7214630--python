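"""Exception hierarchy shared by all mecfes modules."""


class MecfesError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MecfesError, ValueError):
    """A parameter set violates its declared invariants."""


class ShapeError(MecfesError, ValueError):
    """Array lengths or bin counts are inconsistent."""


class ParseError(MecfesError, ValueError):
    """A signal/table file could not be parsed."""


class ValidationError(MecfesError, ValueError):
    """Questionnaire data outside its declared range."""
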