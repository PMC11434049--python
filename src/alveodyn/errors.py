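"""Exception hierarchy.

Every failure mode of the pipeline raises a subclass of :class:`AlveodynError`
so callers can distinguish bad inputs from bugs.
"""


class AlveodynError(Exception):
    """Base class for all alveodyn errors."""


class DomainError(AlveodynError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class PlacementError(AlveodynError):
    """Alveolar mouths could not be placed on the duct without overlap."""

    def __init__(self, seed: int, n_alveoli: int, attempts: int):
        self.seed = seed
        self.n_alveoli = n_alveoli
        self.attempts = attempts
        super().__init__(
            f"could not place {n_alveoli} alveolar mouths without overlap "
            f"after {attempts} attempts (placement_seed={seed}); reduce "
            f"n_alveoli or alveolar_radius, or try another seed"
        )


class DegenerateResolutionError(AlveodynError):
    """Voxel spacing too coarse: a structure occupies too few voxels."""


class ContrastError(AlveodynError):
    """Grayscale image has no usable air/tissue contrast."""


class NoStructureError(AlveodynError):
    """A binary mask contains no foreground to label."""


class GridMismatchError(AlveodynError):
    """Two volumes that must share a voxel grid do not."""


class UnknownLabelError(AlveodynError, KeyError):
    """Requested label is not present in the volume."""


class ClosednessError(AlveodynError):
    """Mesh operation requires a closed (watertight) surface."""


class ManifoldFailureError(ClosednessError):
    """Surface extraction produced an open or non-manifold mesh."""


class NotAttachedError(AlveodynError):
    """Alveolus has no shared aperture with the duct lumen."""


class DegenerateAngleError(AlveodynError):
    """Angle is undefined (coincident points)."""


class UndefinedThicknessError(AlveodynError):
    """No septal tissue ridge exists for the requested alveolus."""


class PairingError(AlveodynError):
    """Records cannot be paired across respiratory states."""


class DegenerateVarianceError(AlveodynError):
    """Zero standard error with a nonzero effect: t is undefined."""


class InsufficientGroupsError(AlveodynError):
    """A between-group test needs at least two groups."""


class SchemaError(AlveodynError):
    """Input table is missing required columns."""
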