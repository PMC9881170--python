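"""Exception hierarchy shared across the package.

Every error raised on invalid user input derives from :class:`MitoinitError`,
so callers (and the CLI) can map failure categories to exit codes.
"""


class MitoinitError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class InvalidConfigError(MitoinitError, ValueError):
    """A simulation or analysis configuration violates its invariants."""

    exit_code = 3


class InvalidMixError(MitoinitError, ValueError):
    """A species mixture is empty or its fractions do not sum to one."""

    exit_code = 3


class InvalidInputError(MitoinitError, ValueError):
    """A data file or in-memory input is malformed or inconsistent."""

    exit_code = 4


class UndefinedACFError(MitoinitError, ValueError):
    """Autocorrelation is undefined (constant-zero signal)."""

    exit_code = 5


class FitFailureError(MitoinitError, RuntimeError):
    """A curve fit failed to converge or the data do not decay."""

    exit_code = 5


class UndefinedResultError(MitoinitError, ValueError):
    """A requested quantity is undefined for the given inputs
    (zero denominator, empty burst list, empty library...)."""

    exit_code = 5


class AmbiguousAnnotationError(MitoinitError, ValueError):
    """Gene counting windows overlap without a declared overlap region."""

    exit_code = 4
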