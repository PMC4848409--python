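"""Exception hierarchy shared across the package."""


class OncotreesError(Exception):
    """Base class for all package errors."""


class MatrixFormatError(OncotreesError, ValueError):
    """Input table could not be parsed as requested (names offending row/column)."""


class ValidationError(OncotreesError, ValueError):
    """A domain invariant was violated (duplicate names, non-binary entry, ...)."""


class ConstraintError(OncotreesError, ValueError):
    """Requested construction is infeasible (names the violated bound)."""


class CapabilityError(OncotreesError, ValueError):
    """Problem size exceeds an exact-enumeration bound."""


class UserInputError(OncotreesError, ValueError):
    """CLI-level user error; rendered as a message, never a traceback."""
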