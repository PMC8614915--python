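"""Exception hierarchy shared across the package."""


class FrontloadError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FrontloadError):
    """A table is missing required columns/samples or has extras."""


class TableParseError(FrontloadError):
    """A cell value cannot be parsed (non-integer count, negative value...)."""


class ContrastSpecError(FrontloadError):
    """A contrast references groups absent from the sample sheet, or the
    contrast quartet handed to the classifier is malformed."""


class UndefinedRatioError(FrontloadError):
    """A ratio or percentage has a zero denominator."""


class DomainError(FrontloadError):
    """An input value lies outside its mathematical domain."""
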