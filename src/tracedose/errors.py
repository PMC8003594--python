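"""Exception types shared across the pipeline."""


class TracedoseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(TracedoseError, ValueError):
    """An input violates a documented precondition or invariant."""


class InsufficientDataError(TracedoseError, ValueError):
    """Too few points (or distinct timepoints) to identify the model."""


class DivergentIntegralError(TracedoseError, ValueError):
    """A closed-form time integral does not converge (nonpositive rate)."""


class MissingSValueError(TracedoseError, KeyError):
    """A required (source, target) S-value entry is absent from the table."""

    def __init__(self, source: str, target: str):
        self.source = source
        self.target = target
        super().__init__(f"no S-value entry for source={source!r} -> target={target!r}")


class OrganMappingError(TracedoseError, KeyError):
    """An organ cannot be mapped between species tables."""
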