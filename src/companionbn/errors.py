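"""Typed exceptions shared across the package."""


class CompanionError(Exception):
    """Base class for all companionbn errors."""


class ModelFormatError(CompanionError):
    """A model or scenario document could not be parsed (names the offending key)."""


class ModelValidationError(CompanionError):
    """A model failed validation; carries the full report."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "model validation failed with %d violation(s):\n%s"
            % (len(report), "\n".join(f"  - {v}" for v in report))
        )


class DegenerateElicitationError(CompanionError):
    """All chips/counts are zero: no distribution can be formed."""


class InconsistentEvidenceError(CompanionError):
    """Observed answers have zero likelihood under every latent level.

    Raised only for structural zeros (exact 0 cells in an elicited table),
    never for floating-point underflow: products are accumulated in log space.
    """


class ParameterError(CompanionError):
    """A numeric parameter is out of its admissible range (e.g. alpha outside [0,1])."""


class ContextError(CompanionError):
    """Unknown patient context profile."""


class StructureError(CompanionError):
    """The directed structure is not acyclic or otherwise malformed."""


class OracleScopeError(CompanionError):
    """The joint state space is too large for brute-force enumeration."""


class ScenarioError(CompanionError):
    """An in silico scenario is invalid against the model."""
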