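import numpy as np
import pytest

from spindletomo.core import (
    ChromosomeMass,
    Ellipsoid,
    Filament,
    PB_PROXIMAL,
    PN_PROXIMAL,
    ReconstructionSlab,
    SpindleScene,
)


def straight(fid, p0, p1, n=2):
    """Straight filament from p0 to p1 with n vertices."""
    pts = np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)
    return Filament(fid, pts)


def two_mass_scene(
    filaments,
    separation_nm=2540.0,
    semi_axes=(500.0, 800.0, 700.0),
    slab=None,
    stage_tag="test",
):
    """Axis-aligned scene: masses at +-separation/2 on X, axis = +X."""
    half = separation_nm / 2.0
    masses = [
        ChromosomeMass(PB_PROXIMAL, Ellipsoid([-half, 0, 0], semi_axes)),
        ChromosomeMass(PN_PROXIMAL, Ellipsoid([half, 0, 0], semi_axes)),
    ]
    if slab is None:
        slab = ReconstructionSlab([-5000, -2500, -2000], [5000, 2500, 2000])
    return SpindleScene(
        slab=slab,
        axis=[1.0, 0.0, 0.0],
        masses=masses,
        filaments=list(filaments),
        stage_tag=stage_tag,
    )


@pytest.fixture
def scene_factory():
    return two_mass_scene


@pytest.fixture
def straight_filament():
    return straight
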