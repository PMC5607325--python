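"""Exception types shared across the package."""


class VentlimError(Exception):
    """Base class for all package errors."""


class ModelValidationError(VentlimError):
    """A food-web model violates a structural invariant."""


class ModelParseError(VentlimError):
    """A declarative model file could not be parsed.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CompileError(VentlimError):
    """A constraint sub-compiler could not build its rows."""


class InfeasibleError(VentlimError):
    """The constraint system admits no solution.

    ``certificate`` lists the provenance tags of an irreducible set of
    mutually inconsistent rows, when one could be isolated.
    """

    def __init__(self, message: str, certificate: list[str] | None = None):
        self.certificate = certificate or []
        if self.certificate:
            message += " (conflicting rows: " + ", ".join(self.certificate) + ")"
        super().__init__(message)


class UnboundedError(VentlimError):
    """The feasible polytope is unbounded along at least one flow."""

    def __init__(self, message: str, flows: list[str] | None = None):
        self.flows = flows or []
        if self.flows:
            message += " (unbounded flows: " + ", ".join(self.flows) + ")"
        super().__init__(message)
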