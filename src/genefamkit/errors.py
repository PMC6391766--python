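"""Exception hierarchy shared across the toolkit."""


class GenefamkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(GenefamkitError, ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class InvalidCodonError(InvalidSequenceError):
    """A codon is a stop codon or contains ambiguous/invalid bases."""


class AllPathsThroughStopError(GenefamkitError, ValueError):
    """Every mutational pathway between two codons passes through a stop."""


class SaturationError(GenefamkitError, ValueError):
    """A difference proportion is >= 3/4, so the corrected distance is undefined.

    When raised from a full pairwise estimate the partially computed result
    (counts, proportions, with the saturated distance set to NaN) is attached
    as ``partial``.
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class EmptyAlignmentError(GenefamkitError, ValueError):
    """No codon columns remain after masking gaps/ambiguities/stops."""


class EmptyOverlapError(GenefamkitError, ValueError):
    """Two aligned sequences share no comparable (ungapped) site."""


class ConfigurationError(GenefamkitError, ValueError):
    """Invalid user-supplied configuration or parameter."""
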