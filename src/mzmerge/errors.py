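"""Exception hierarchy shared across mzmerge.

The CLI maps these onto exit codes: validation errors -> 2, I/O errors -> 3
(plain OSError), computation errors -> 4.
"""


class MzMergeError(Exception):
    """Base class for all mzmerge errors."""


class ValidationError(MzMergeError):
    """Input violates a structural contract (bad header, duplicate column...)."""


class TableFormatError(ValidationError):
    """A feature table file could not be parsed."""


class ConfigurationError(ValidationError):
    """Inconsistent run configuration (e.g. varying replicate counts)."""


class ComputationError(MzMergeError):
    """A stage ran but produced an unusable result (e.g. all samples filtered)."""
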