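import numpy as np
import pytest

from alveodyn import phantom as ph
from alveodyn.labels import LabeledVolume


def desk_spec(**overrides) -> ph.PhantomSpec:
    """Small gas-exchange unit that fits a ~100³ grid at 0.65 µm."""
    base = dict(
        duct_radius=10.0,
        duct_length=40.0,
        n_alveoli=4,
        alveolar_radius=10.0,
        alveolar_dispersion=0.08,
        mouth_fraction=0.45,
        placement_seed=3,
        deformation_mode="isotropic",
        volume_ratio=1.5,
        voxel_spacing=0.65,
    )
    base.update(overrides)
    return ph.PhantomSpec(**base)


class SphereSolid(ph.Solid):
    """Analytic ball, for voxelization oracles."""

    def __init__(self, radius, center=(0.0, 0.0, 0.0)):
        self.r = float(radius)
        self.center = np.asarray(center, dtype=float)

    def contains(self, pts):
        return ((pts - self.center) ** 2).sum(axis=1) <= self.r**2

    @property
    def bounds(self):
        return self.center - self.r, self.center + self.r


@pytest.fixture(scope="session")
def desk_unit():
    """One deterministic isotropic desk-scale phantom with truth."""
    spec = desk_spec()
    exp, insp, truth = ph.generate_unit(spec)
    return spec, exp, insp, truth


@pytest.fixture(scope="session")
def desk_labels(desk_unit):
    """Directly voxelized label volumes of the desk phantom, both states."""
    spec, exp, insp, _ = desk_unit
    return (
        ph.voxelize(exp, spec.voxel_spacing),
        ph.voxelize(insp, spec.voxel_spacing),
    )


def make_volume(voxels, spacing=1.0, **kw) -> LabeledVolume:
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    return LabeledVolume(np.asarray(voxels, dtype=np.int32), spacing, **kw)


def ball_mask(shape, center, radius):
    zz, yy, xx = np.indices(shape)
    return (
        (zz - center[0]) ** 2
        + (yy - center[1]) ** 2
        + (xx - center[2]) ** 2
    ) <= radius**2
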