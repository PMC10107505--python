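"""Exception hierarchy.

Every error raised by this package derives from :class:`ProthermError` so
callers (and the CLI) can distinguish computation failures from bugs.
"""


class ProthermError(Exception):
    """Base class for all protherm errors."""


class InputError(ProthermError, ValueError):
    """Invalid user-supplied data (empty cloud, non-positive dimension, ...)."""


class GeometryError(InputError):
    """Degenerate point cloud (coincident points, zero extent)."""


class DomainError(ProthermError, ValueError):
    """Argument outside the mathematical domain of an analytic relation."""


class NoRootError(DomainError):
    """The requested root equation has no solution in the valid interval."""


class FitError(ProthermError, RuntimeError):
    """Least-squares fit failed to converge or produced an invalid optimum."""


class SolverError(ProthermError, RuntimeError):
    """Numerical PDE solver instability or blow-up."""


class DataError(InputError):
    """Malformed or inconsistent input file content."""


class ConfigError(InputError):
    """Invalid run configuration (missing box size, bad option combination)."""
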