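"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: UsageError/FormatError/ValidationError -> 2,
anything else -> 1.
"""


class HemotypeError(Exception):
    """Base class for all package errors."""

    code = "INTERNAL_ERROR"


class CatalogFormatError(HemotypeError):
    """A catalog table is syntactically malformed (bad column, bad literal)."""

    code = "CATALOG_FORMAT"


class CatalogValidationError(HemotypeError):
    """A catalog table violates a semantic invariant (duplicate id, dangling ref)."""

    code = "CATALOG_INVALID"


class UsageError(HemotypeError):
    """The caller asked for something the inputs cannot provide."""

    code = "USAGE"


class LowControlDepthError(HemotypeError):
    """Control-region depth too low for a reliable coverage ratio."""

    code = "LOW_CONTROL"
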