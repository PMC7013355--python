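import numpy as np
import pytest

from plcpd import OcclusionSector, PhantomSpec, SimilarityTransform, make_phantom_pair
from scipy.spatial.transform import Rotation


def small_phantom_spec(seed=3, occluded=True, transform=None, speckle=1.0):
    """64³ phantom used by image-path tests (fast but realistic)."""
    sectors_a = (OcclusionSector((1.0, 0.0, 0.0), 90.0, 0.0),) if occluded else ()
    sectors_b = (OcclusionSector((0.0, 1.0, 0.0), 90.0, 0.0),) if occluded else ()
    return PhantomSpec(
        shape=(64, 64, 64),
        spacing=(0.8, 0.8, 0.8),
        semi_axes=(18.0, 16.0, 14.0),
        shell_thickness=2.0,
        speckle=speckle,
        sectors_a=sectors_a,
        sectors_b=sectors_b,
        transform=transform,
        seed=seed,
    )


def modest_transform(angle_deg=18.0, translation=(4.0, -3.0, 2.0), scale=1.0):
    axis = np.array([0.2, 0.5, 0.84])
    axis /= np.linalg.norm(axis)
    return SimilarityTransform(
        rotation=Rotation.from_rotvec(np.radians(angle_deg) * axis).as_matrix(),
        scale=scale,
        translation=np.asarray(translation, float),
    )


@pytest.fixture(scope="session")
def phantom_pair_64():
    """One occluded, transformed 64³ phantom pair shared across tests."""
    spec = small_phantom_spec(seed=3, transform=modest_transform())
    return spec, make_phantom_pair(spec)


@pytest.fixture(scope="session")
def rotation_error_deg():
    def _err(r_est, r_true):
        d = r_est @ r_true.T
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(d).as_rotvec()))
        )

    return _err
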