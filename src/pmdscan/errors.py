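"""Exception hierarchy for pmdscan.

All library errors derive from :class:`PmdscanError` so callers (and the
CLI) can catch one base class.
"""


class PmdscanError(Exception):
    """Base class for all pmdscan errors."""


class ParseError(PmdscanError):
    """A text input could not be parsed; the message carries the line number."""


class ChromosomeNotFoundError(PmdscanError):
    """A record names a chromosome absent from the reference sizes."""


class OrderingError(PmdscanError):
    """Genomic records are not sorted by position within a chromosome."""


class DataError(PmdscanError):
    """The input is well-formed but carries too little or degenerate data."""


class ConsistencyError(PmdscanError):
    """Two objects that must describe the same genome/binning disagree."""
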