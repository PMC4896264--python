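"""Exception hierarchy for maldikit."""


class MaldikitError(Exception):
    """Base class for all maldikit errors."""


class ParseError(MaldikitError):
    """A cell in an input file could not be parsed as a number."""


class FormatError(MaldikitError):
    """An input file violates the block peak-list layout (e.g. odd column count)."""


class ValidationError(MaldikitError):
    """A value or parameter violates a documented invariant."""


class NormalizationPeakNotFound(MaldikitError):
    """No peak lies within the tolerance window around the normalization m/z."""
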