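"""Exception hierarchy shared across the package."""


class AtquantError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(AtquantError):
    """Two volumes that must share shape/spacing/origin do not."""


class DimensionalityError(AtquantError):
    """An image on disk is not a 3D scalar volume."""


class EmptyMaskError(AtquantError):
    """An operation that requires a nonempty mask received an empty one."""


class EmptySegmentationError(AtquantError):
    """Lung segmentation found no acceptable low-attenuation component."""


class FoldingError(AtquantError):
    """A displacement field has non-positive Jacobian determinant somewhere."""

    def __init__(self, n_folded: int):
        self.n_folded = n_folded
        super().__init__(f"deformation folds over: {n_folded} voxels with det <= 0")


class DivergenceError(AtquantError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch}")


class ConfigError(AtquantError):
    """A configuration value failed schema validation."""
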