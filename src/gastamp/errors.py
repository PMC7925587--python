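"""Exception hierarchy for gastamp."""


class GasTampError(Exception):
    """Base class for all gastamp errors."""


class InvalidGeometryError(GasTampError):
    """Eye-model parameters violate a geometric invariant."""


class OutOfSurfaceError(GasTampError):
    """An arc distance runs past the posterior pole."""


class OffSurfaceError(GasTampError):
    """A query point does not lie on the spherical wall."""


class UnknownPositionError(GasTampError):
    """Position name is not one of the six supported postures."""


class InvalidParamsError(GasTampError):
    """Physical parameters violate an invariant (e.g. rho_gas >= rho_water)."""


class NonConvergenceError(GasTampError):
    """A numerical solve failed to converge."""


class ResolutionTooLowError(GasTampError):
    """Mesh or voxel resolution too coarse for the requested tolerance."""


class MemoryGuardError(GasTampError):
    """Voxel resolution exceeds the configured memory cap."""


class MismatchedModelError(GasTampError):
    """Region / interface evaluated against a different eye model."""


class MisalignedGridError(GasTampError):
    """Computed and reference tables do not share the same grid."""


class FixtureCorruptionError(GasTampError):
    """Packaged reference table fails its load-time invariants."""


class EmptyBreakSetError(GasTampError):
    """Position recommendation called with no break quadrants."""


class ConfigError(GasTampError):
    """Run configuration failed validation."""
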