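"""Exception hierarchy.

Every failure mode a caller may want to branch on carries a stable
``error_class`` string, which the CLI serialises into machine-readable
error output.
"""


class KinpotError(Exception):
    """Base class for all package errors."""

    error_class = "error"


class InputError(KinpotError):
    """Malformed or inconsistent user input (files, arrays, configs)."""

    error_class = "input_error"


class DomainError(KinpotError):
    """Argument outside the mathematical/physical domain of an operation."""

    error_class = "domain_error"


class IntegrationError(KinpotError):
    """The stiff ODE solver failed to converge."""

    error_class = "integration_error"


class QSSAValidityError(KinpotError):
    """Quasi-steady-state mode requested on a grid too fine to justify it."""

    error_class = "qssa_invalid"


class NoInflectionError(KinpotError):
    """No induction-period inflection detectable in the potential trace.

    This is the documented failure mode for "slow" antioxidants and for
    inert additions (e.g. KCl controls): the potential just keeps rising
    and the derivative never shows a dominant post-addition maximum.
    """

    error_class = "no_inflection"


class InsufficientDataError(KinpotError):
    """Too few usable samples for a regression or slope estimate."""

    error_class = "insufficient_data"


class MediatorCapacityError(DomainError):
    """Added antioxidant would exhaust the ferricyanide mediator."""

    error_class = "mediator_capacity"


class NotApplicableError(KinpotError):
    """The estimation method does not apply to this compound.

    Raised for species flagged ``mediator_compatible=False`` (e.g.
    thiadiazines, which transform into mercaptopyrazoles with their own
    slow hexacyanoferrate kinetics and therefore cannot be assayed
    through the mediator cell).
    """

    error_class = "not_applicable"


class UndefinedCorrelationError(KinpotError):
    """Pearson correlation undefined (zero variance in one variable)."""

    error_class = "undefined_correlation"
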