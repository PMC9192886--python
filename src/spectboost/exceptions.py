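"""Exception types shared across the package."""


class SpectBoostError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(SpectBoostError):
    """Requested geometry does not fit the voxel grid."""


class AlignmentError(SpectBoostError):
    """Volumes expected on a common grid disagree in shape or spacing."""


class ContractError(SpectBoostError):
    """An API contract was violated (wrong modality, method, count...)."""


class FormatError(SpectBoostError):
    """A file could not be parsed as the expected format."""


class NormalizationError(SpectBoostError):
    """Normalization is undefined for this input (e.g. zero mean)."""


class PlacementError(SpectBoostError):
    """Random object placement failed after bounded retries."""


class ShapeError(SpectBoostError):
    """Spatial shape incompatible with the network topology."""
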