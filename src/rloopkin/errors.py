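"""Exception hierarchy shared across the package."""


class RloopkinError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RloopkinError):
    """A tabular input violates the expected column/type schema."""


class ProtocolError(RloopkinError):
    """A rotation protocol is inconsistent with the trace it describes."""


class FitError(RloopkinError):
    """A model fit could not be performed (distinct from non-convergence,
    which is reported through result flags)."""


class FlankFitError(RloopkinError):
    """A rotation-curve flank could not be fitted (too few points past the
    buckling shoulder, or the selected region is not a valid flank)."""


class InvalidPairError(RloopkinError):
    """A reference/R-loop rotation-curve pair is not comparable
    (e.g. flank slopes differ by more than the allowed mismatch)."""
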