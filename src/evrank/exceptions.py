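"""Exception and warning hierarchy.

Three error classes mirror the three ways an analysis can fail before any
mathematics runs: the configuration does not describe the table
(:class:`ConfigurationError`), a cell cannot be used (:class:`DataError`),
or the assembled problem violates a model invariant
(:class:`ValidationError`).
"""


class EVRankError(Exception):
    """Base class for all evrank errors."""


class ConfigurationError(EVRankError):
    """Factor configuration does not match the data table (missing/extra/duplicate columns, bad direction...)."""


class DataError(EVRankError):
    """A cell failed to parse or is non-finite; message carries row/column coordinates."""


class ValidationError(EVRankError):
    """A model invariant is violated (positivity, weight sum, duplicate names...)."""


class EVRankWarning(UserWarning):
    """Base warning: physically suspect but representable values (negative internal
    content, recovery above 100 %, degenerate identical alternatives)."""
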