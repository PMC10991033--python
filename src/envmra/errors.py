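"""Exception hierarchy for envmra.

All library errors derive from :class:`EnvMRAError` so callers can catch one
base class; the leaves additionally subclass the matching builtin
(``ValueError`` / ``RuntimeError``) for idiomatic handling.
"""


class EnvMRAError(Exception):
    """Base class for all envmra errors."""


class InvalidParameterError(EnvMRAError, ValueError):
    """A model or filter parameter violates its constraints."""


class InvalidInputError(EnvMRAError, ValueError):
    """Input data violates a precondition (negative amplitudes, empty sets...)."""


class InvalidSpecError(EnvMRAError, ValueError):
    """A phantom specification is internally inconsistent or infeasible."""


class ContractError(EnvMRAError, ValueError):
    """Data handed between pipeline stages violates an interface contract."""


class NumericalError(EnvMRAError, RuntimeError):
    """A numerical operation (matrix inversion, optimisation) failed."""


class SchemaError(EnvMRAError, ValueError):
    """A serialized artifact (sidecar, filter file) has a malformed schema."""


class UndefinedMetricError(EnvMRAError, ValueError):
    """A requested metric is undefined for the given data (empty denominator)."""
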