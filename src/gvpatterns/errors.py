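"""Exception types shared across the package."""


class GvPatternsError(Exception):
    """Base class for all package errors."""


class FormatError(GvPatternsError, ValueError):
    """An input file does not match the expected schema."""


class ConfigError(GvPatternsError, ValueError):
    """A configuration value is invalid or internally inconsistent."""


class DegenerateDataError(GvPatternsError, ValueError):
    """The data cannot support the requested operation (e.g. all-identical
    windows with k >= 2, or an unsatisfiable dendrogram cut)."""
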