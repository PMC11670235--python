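"""Exception hierarchy for mexdiff."""


class MexdiffError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MexdiffError, ValueError):
    """Invalid parameter set or simulation configuration."""


class DomainError(MexdiffError, ValueError):
    """An input falls outside the physical/geometric domain of an operation."""


class SingularSystemError(MexdiffError, ValueError):
    """The two-region mixture system has no unique solution."""


class InsufficientDataError(MexdiffError, ValueError):
    """Too few data points (e.g. occupied profile bins) for a fit."""


class ComparisonError(MexdiffError, ValueError):
    """Two series cannot be compared (e.g. disjoint time supports)."""


class FrapFitError(MexdiffError, RuntimeError):
    """A FRAP recovery curve could not be fitted; carries diagnostics.

    Parameters
    ----------
    message:
        Human-readable failure reason.
    diagnostics:
        Optional mapping with intermediate quantities (pre-bleach level,
        bleach depth, recovered fraction, ...) to help debugging.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
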