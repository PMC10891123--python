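"""Exception types shared across the pipeline."""


class PolyloadError(Exception):
    """Base class for all polyload errors."""


class InvalidParameterError(PolyloadError, ValueError):
    """A parameter is outside its documented domain."""


class EmptyInputError(PolyloadError, ValueError):
    """An operation received an empty histogram/track/sample."""


class NoSignalError(PolyloadError, RuntimeError):
    """The data carry no detectable signal (e.g. a monotone k-mer spectrum)."""


class FrameError(PolyloadError, ValueError):
    """A codon alignment is not in frame (length not divisible by 3)."""


class OrderingError(PolyloadError, ValueError):
    """Positions that must be sorted are not."""


class FormatError(PolyloadError, ValueError):
    """An input file lacks a required field (e.g. DP in a VCF)."""


class CoordinateError(PolyloadError, ValueError):
    """A genomic coordinate falls outside its sequence."""


class InvalidStateError(PolyloadError, RuntimeError):
    """An operation was called on an object in an unusable state."""


class ConsistencyError(PolyloadError, ValueError):
    """Jointly supplied inputs disagree (e.g. sample sets differ)."""
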