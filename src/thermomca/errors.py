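"""Exception hierarchy for thermomca."""


class ThermomcaError(Exception):
    """Base class for all package errors."""


class SchemaError(ThermomcaError):
    """A model file violates the JSON model schema."""


class ValidationError(ThermomcaError):
    """A constructed object violates its invariants."""


class InfeasibleError(ThermomcaError):
    """A TFA problem (or a variability subproblem) is infeasible."""


class SteadyStateError(ThermomcaError):
    """No steady state could be found for a kinetic model."""


class SingularSystemError(ThermomcaError):
    """A linear system required by the control analysis is singular."""
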