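import numpy as np
import pytest

from germseg import SyntheticSceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A quick 4-nucleus scene shared by read-only tests."""
    spec = SyntheticSceneSpec(volume_shape_vox=(28, 160, 160), n_nuclei=4, seed=11)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def ten_nucleus_labels():
    """Ground-truth labels of a clean 10-nucleus scene (known-answer tests)."""
    spec = SyntheticSceneSpec(
        volume_shape_vox=(48, 200, 200),
        n_nuclei=10,
        noise_gaussian_sd=0.0,
        noise_poisson_scale=0.0,
        psf_sigma_um=0.0,
        seed=3,
    )
    _, labels, _ = generate_scene(spec)
    return labels


def antialiased_disk(radius_px):
    """2D disk with area-sampled (soft) edges; value 0.5 at the true rim.

    Hard-edged rasterization quantizes the diameter to whole input pixels,
    which at coarse pixel sizes dominates the sub-pixel rescaling error this
    fixture is meant to expose."""
    n = int(np.ceil(2 * radius_px)) + 17
    n += 1 - n % 2  # odd, so the center falls on a pixel
    c = n // 2
    yy, xx = np.ogrid[:n, :n]
    dist = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
    return np.clip(radius_px - dist + 0.5, 0.0, 1.0).astype(np.float32)


def make_ball_volume(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    """Binary ball rasterized on an (optionally anisotropic) voxel grid."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center[0]) * spacing[0]) ** 2
        + ((yy - center[1]) * spacing[1]) ** 2
        + ((xx - center[2]) * spacing[2]) ** 2
    )
    return (d2 <= radius**2).astype(np.int32)
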