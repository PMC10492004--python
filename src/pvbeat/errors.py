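"""Exception hierarchy.

Every failure mode carries a ``stage`` label so that beat-level rejection
records can say *where* in the chain (signal conditioning, flow synthesis,
isovolumic fit, loop mechanics, simulation) a beat was lost.
"""

from __future__ import annotations


class PVBeatError(Exception):
    """Base class for all package errors."""

    stage: str = "generic"


class FormatError(PVBeatError):
    """Input file does not have the expected columns/layout."""

    stage = "io"


class DataError(PVBeatError):
    """Input values violate a data precondition (non-monotone time, NaNs...)."""

    stage = "io"


class ConfigurationError(PVBeatError):
    """A configuration value is out of its allowed range."""

    stage = "config"


class DomainError(PVBeatError):
    """A scalar argument is outside its mathematical domain."""

    stage = "mechanics"


class GeometryError(PVBeatError):
    """A degenerate geometric construction (zero-base triangle, zero-SV loop)."""

    stage = "mechanics"


class LandmarkError(PVBeatError):
    """Flow landmarks could not be located or are mis-ordered; beat rejected."""

    stage = "flow_synthesis"


class FitWindowError(PVBeatError):
    """Isovolumic fit limbs are empty or too short; beat rejected."""

    stage = "isovolumic_fit"


class FitError(PVBeatError):
    """Isovolumic curve fit failed to converge or is implausible."""

    stage = "isovolumic_fit"


class TangencyError(PVBeatError):
    """No valid tangent line from the isovolumic peak to the loop."""

    stage = "mechanics"


class SimulationError(PVBeatError):
    """The forward model failed to reach a periodic steady state."""

    stage = "simulator"
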