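"""Exception types shared across the pipeline."""


class CookietalkError(Exception):
    """Base class for package errors."""


class EmptyTranscriptError(CookietalkError):
    """A transcript contains no usable participant speech."""


class MissingDemographicsError(CookietalkError):
    """Age or education is absent; demographic features cannot be built."""


class BackendUnavailableError(CookietalkError):
    """A pluggable backend (grammar checker, embedder) cannot be reached."""


class DimensionMismatchError(CookietalkError):
    """Two embedding vectors of different dimension were compared."""


class ZeroVectorError(CookietalkError):
    """Cosine similarity requested against an all-zero vector."""


class UndefinedDiversityError(CookietalkError):
    """Lexical diversity requested for an empty vocabulary."""


class UndefinedCorrelationError(CookietalkError):
    """Rank correlation requested for a constant input."""


class StratificationError(CookietalkError):
    """A class is too small to fill every cross-validation fold."""
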