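"""Exception hierarchy shared across the package."""


class LpukitError(Exception):
    """Base class for all package-specific errors."""


class SelectorError(LpukitError, ValueError):
    """Base class for selector parsing/expansion errors."""


class SelectorSyntaxError(SelectorError):
    """Malformed selector text. Carries the 0-based position of the offence."""

    def __init__(self, message: str, pos: int | None = None):
        self.pos = pos
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)


class WildcardError(SelectorError):
    """Operation requires a wildcard-free selector."""


class CardinalityError(SelectorError):
    """Elementwise join of selectors with unequal cardinality."""


class PatternError(LpukitError, ValueError):
    """Base class for connectivity-pattern violations."""


class OverlapError(PatternError):
    """The two interfaces of a pattern share an identifier."""


class UnknownPortError(LpukitError, KeyError):
    """A selected identifier does not exist in the addressed object."""

    def __init__(self, identifier):
        self.identifier = identifier
        super().__init__(f"unknown port: {identifier}")

    def __str__(self):  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class InterfaceMismatchError(PatternError):
    """Port addressed through the wrong pattern interface."""


class FanInError(PatternError):
    """Destination port already has a source (fan-in is prohibited)."""


class TransmissionMismatchError(PatternError):
    """Connection endpoints carry different transmission kinds."""


class DirectionError(PatternError):
    """Connection endpoints have the wrong pattern-relative directions."""


class SameInterfaceError(PatternError):
    """Connection endpoints lie on the same pattern interface."""


class AttributeConflictError(PatternError):
    """Re-setting port attributes would violate invariants of existing connections."""


class ValidationError(LpukitError, ValueError):
    """An LPU spec failed validation; carries the report."""

    def __init__(self, report):
        self.report = report
        super().__init__("invalid LPU spec:\n" + "\n".join(report.violations))


class DuplicateIdError(LpukitError, ValueError):
    """An LPU id or model name is already registered."""


class IncompatibilityError(LpukitError, ValueError):
    """Pattern/LPU compatibility check failed; carries both reports."""

    def __init__(self, report0, report1):
        self.report0 = report0
        self.report1 = report1
        lines = ["pattern/LPU incompatibility:"]
        lines += ["  interface 0: " + m for m in report0.mismatches]
        lines += ["  interface 1: " + m for m in report1.mismatches]
        super().__init__("\n".join(lines))


class RoutingError(LpukitError, ValueError):
    """Route compilation failed (e.g. cross-pattern fan-in)."""


class LPUStepError(LpukitError, RuntimeError):
    """A step hook raised; wraps the original with LPU id and step index."""

    def __init__(self, lpu_id: str, step: int, cause: BaseException):
        self.lpu_id = lpu_id
        self.step = step
        super().__init__(f"LPU {lpu_id!r} failed at step {step}: {cause!r}")
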