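"""Exception hierarchy shared across the pipeline stages."""


class OrthoverlapError(Exception):
    """Base class for all hard errors raised by this package."""


class FormatError(OrthoverlapError):
    """An input file violates its documented layout."""


class ValidationError(OrthoverlapError):
    """Well-formed input violates a domain constraint."""
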