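"""Exception hierarchy shared across the package."""


class PdspeechError(Exception):
    """Base class for all package errors."""


class FormatError(PdspeechError):
    """Unreadable or unsupported input file."""


class EmptyInputError(PdspeechError):
    """An operation received zero-length or effectively empty input."""


class ArgumentError(PdspeechError, ValueError):
    """A parameter is outside its documented domain."""


class NotComputableError(PdspeechError):
    """The requested quantity is undefined for this signal (e.g. HNR of noise)."""


class InsufficientEventsError(PdspeechError):
    """Too few detected events to form the requested dispersion statistics."""


class InsufficientPhonationError(PdspeechError):
    """Less voiced material than the minimum required for sustained-vowel analysis."""


class InsufficientCyclesError(PdspeechError):
    """Fewer than two alternation cycles detected in an /i/-/u/ recording."""


class NormalizationError(PdspeechError):
    """A sex stratum lacks the healthy-control data needed for z-scoring."""


class CollinearityError(PdspeechError):
    """A design or covariate matrix is rank deficient."""


class StratificationError(PdspeechError):
    """A cross-validation fold ended up with a single class during training."""


class DegenerateNodeError(PdspeechError):
    """A node time series has zero variance, so correlations are undefined."""


class InconsistentInputError(PdspeechError):
    """Inputs contradict each other (e.g. pauses longer than the recording)."""
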