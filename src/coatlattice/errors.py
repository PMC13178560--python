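"""Exception hierarchy for the coatlattice pipeline."""


class CoatLatticeError(Exception):
    """Base class for all pipeline errors."""


class InvalidAngleError(CoatLatticeError, ValueError):
    """Euler angles are non-finite or malformed."""


class InvalidRotationError(CoatLatticeError, ValueError):
    """A matrix is not orthonormal with determinant +1 within tolerance."""


class FitDegenerateError(CoatLatticeError, ValueError):
    """Cylinder fit input is collinear or spans too little arc."""


class UnmappableParticleError(CoatLatticeError, ValueError):
    """A particle lies on (or too close to) the tube axis and has no azimuth."""


class AnnotationError(CoatLatticeError, ValueError):
    """A tubule annotation violates its invariants."""


class TubeTooThinError(CoatLatticeError, ValueError):
    """Requested seed spacing does not fit even once around the tube."""


class ConfigError(CoatLatticeError, ValueError):
    """A lattice generator configuration violates its invariants."""


class LatticeNotFoundError(CoatLatticeError, RuntimeError):
    """Fewer than two resolvable displacement peaks; no 2D lattice."""


class NotALateralContactError(CoatLatticeError, ValueError):
    """The particle pair is an axial (same-stripe) contact, not inter-stripe."""


class StaleLinkageError(CoatLatticeError, ValueError):
    """Linkage members are farther apart than the expected contact distance allows."""


class FormatError(CoatLatticeError, ValueError):
    """A particle-table file is missing required columns or has bad cells."""
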