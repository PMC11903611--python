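"""Exception hierarchy for the concordance pipeline.

Exit-code mapping used by the CLI: validation-type errors exit 1,
I/O problems exit 2.
"""


class HpaConcordError(Exception):
    """Base class for all package errors."""


class SchemaError(HpaConcordError):
    """An input table is missing a required column or has the wrong shape."""


class TableValidationError(HpaConcordError):
    """A row-level value violates an invariant (negative abundance,
    unparseable level, duplicate key in strict mode, ...)."""


class ConfigurationError(HpaConcordError):
    """A configuration value is invalid (bad probability vector,
    unknown cell type, empty keep set, ...)."""


class InternalConsistencyError(HpaConcordError):
    """Summary counts violate a structural invariant (nesting of
    validation counts, count/percentage mismatch, conservation)."""
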