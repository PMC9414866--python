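"""Exception hierarchy shared across the package."""


class EquithermError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EquithermError):
    """Invalid study design or pipeline configuration."""


class DimensionError(EquithermError):
    """Input too small for the requested window / ROI out of bounds."""


class ParameterError(EquithermError):
    """Invalid entropy or feature parameter (e.g. r = 0 for fuzzy entropy)."""


class UndefinedEntropyError(EquithermError):
    """Sample entropy is undefined because no template matches were found.

    Raised when either match density is exactly zero; distinct from an
    entropy of 0, which means perfect regularity.
    """
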