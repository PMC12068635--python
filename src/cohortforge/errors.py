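"""Exception hierarchy.

Every error raised deliberately by the package derives from
:class:`CohortForgeError`, so callers (and the CLI) can distinguish
engine errors from programming bugs.
"""


class CohortForgeError(Exception):
    """Base class for all cohortforge errors."""


class FormatError(CohortForgeError):
    """An input file could not be parsed (names the file and line)."""


class SchemaError(CohortForgeError):
    """A table is missing required columns or carries unknown ones."""


class ConfigurationError(CohortForgeError):
    """A configuration object or bundled table is invalid."""


class SpecificationError(CohortForgeError):
    """A selection specification is incomplete or self-contradictory."""


class CodeFormatError(CohortForgeError):
    """A clinical code string is empty or not alphanumeric."""


class UnknownCovariateError(CohortForgeError):
    """An explicitly named covariate does not exist in the catalog."""


class ImmutabilityError(CohortForgeError):
    """Attempt to overwrite a versioned, read-only artifact."""


class CompletenessError(CohortForgeError):
    """A dataset column has no dictionary metadata."""


class JoinError(CohortForgeError):
    """A custom-data excerpt cannot be joined (missing universal key)."""


class MigrationError(CohortForgeError):
    """A saved spec uses an unsupported schema version."""
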