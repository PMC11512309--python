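"""Exception hierarchy shared across the pipeline stages."""


class RetroscopeError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(RetroscopeError, ValueError):
    """A configuration or call parameter violates its contract."""


class MissingFeatureError(RetroscopeError, KeyError):
    """A requested annotation label is absent from the bundle."""


class ChromosomeMismatchError(RetroscopeError, ValueError):
    """Site and annotation chromosome namespaces do not agree."""


class MalformedAnnotationError(RetroscopeError, ValueError):
    """Intervals that must be disjoint within a class family overlap."""


class InsufficientDataError(RetroscopeError, ValueError):
    """Too few observations to compute the requested statistic."""


class MissingControlError(RetroscopeError, ValueError):
    """A required control sample (e.g. mock flow sample) is empty or absent."""


class SaturationError(RetroscopeError, ValueError):
    """All droplets positive: Poisson inversion is undefined."""


class MissingReferenceError(RetroscopeError, ValueError):
    """Reference-gene copy number is zero or absent."""


class UndefinedFoldError(RetroscopeError, ValueError):
    """Fold change requested against a zero baseline."""


class UndefinedRatioError(RetroscopeError, ValueError):
    """Active-genome ratio requested with zero copy number."""
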