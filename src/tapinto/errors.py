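"""Exception hierarchy shared across the package.

The CLI maps :class:`InputError` subclasses to exit code 2 and
:class:`DegenerateDataError` to exit code 3.
"""


class TapintoError(Exception):
    """Base class for all package-specific errors."""


class InputError(TapintoError):
    """Malformed or inconsistent user input (file format, values, config)."""


class MatrixFormatError(InputError):
    """Structural problem in an expression matrix file (duplicates, shape)."""


class MatrixValueError(InputError):
    """A cell of the expression matrix is negative, non-numeric or non-finite."""


class RoleConfigError(InputError):
    """Sample-role annotation missing, incomplete, or with unknown labels."""


class DegenerateDataError(TapintoError):
    """Data too degenerate for the requested computation (e.g. < s_min tumors)."""
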