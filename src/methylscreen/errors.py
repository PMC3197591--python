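"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: :class:`DataError`/:class:`InputError` -> 1,
:class:`ConfigurationError` -> 2.
"""


class MethylscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MethylscreenError, ValueError):
    """A parameter or config value violates its documented bounds."""


class DataError(MethylscreenError, ValueError):
    """A data value is invalid (non-finite intensity, out-of-range percent...)."""


class InputError(MethylscreenError, ValueError):
    """Inputs are structurally incompatible (missing reference column,
    mismatched identifiers, empty sample intersection)."""
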