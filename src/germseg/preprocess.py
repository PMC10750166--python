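"""Physical-units preprocessing: rescale nuclei to 30 px, compute anisotropy, blur.

The segmentation backend expects nuclei of roughly 30 px diameter. Given the
user's expected nucleus diameter in µm (default 3.5, typical for pachytene
germline nuclei) and the acquisition pixel size, every slice is resampled
laterally so that one nucleus spans 30 px; the z axis is left untouched and
its coarser sampling is reported to the backend as an anisotropy ratio.
A physically isotropic Gaussian blur (sigma = ``blurfactor`` rescaled pixels
laterally, ``blurfactor / anisotropy`` axially) suppresses the discontinuous
chromatin texture inside nuclei before segmentation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .stacks_io import VoxelGrid3D

__all__ = [
    "TARGET_DIAMETER_PX",
    "PreprocessParams",
    "compute_scale_factor",
    "rescale_xy",
    "compute_anisotropy",
    "gaussian_blur",
]

#: Backend-native object diameter in pixels; all lateral rescaling targets it.
TARGET_DIAMETER_PX = 30

_MIN_OUTPUT_DIM = 4


@dataclasses.dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing knobs.

    diameter_um
        Expected nucleus diameter in µm (default 3.5).
    blurfactor
        Gaussian sigma in rescaled pixels (default 2.5 for chromatin
        staining; 3.5 recommended for deconvolved or synaptonemal-complex
        images). 0 disables blurring.
    """

    diameter_um: float = 3.5
    blurfactor: float = 2.5

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if self.blurfactor < 0:
            raise ValueError("blurfactor must be >= 0")

    @property
    def target_pixel_size_um(self) -> float:
        """Pixel size after rescaling, µm/px (= diameter_um / 30)."""
        return self.diameter_um / TARGET_DIAMETER_PX


def compute_scale_factor(pixel_size_xy_um: float, diameter_um: float) -> float:
    """Lateral scale factor s mapping a ``diameter_um`` object onto 30 px.

    s = 30 * pixel_size_xy_um / diameter_um, so the rescaled pixel size is
    diameter_um / 30 µm/px.
    """
    if not pixel_size_xy_um > 0:
        raise ValueError("pixel_size_xy_um must be positive")
    if not diameter_um > 0:
        raise ValueError("diameter_um must be positive")
    return TARGET_DIAMETER_PX * pixel_size_xy_um / diameter_um


def rescale_xy(grid: VoxelGrid3D, s: float) -> VoxelGrid3D:
    """Resample each z-slice by factor *s* in y and x; z untouched.

    First-order (linear) interpolation; the pixel size is divided by *s* so
    the physical lateral extent is preserved within one output pixel.
    """
    if not s > 0:
        raise ValueError("scale factor must be positive")
    z, y, x = grid.shape
    out_y, out_x = int(round(y * s)), int(round(x * s))
    if min(out_y, out_x) < _MIN_OUTPUT_DIM:
        raise ValueError(
            f"rescaling by {s:g} would shrink a {y}x{x} slice below {_MIN_OUTPUT_DIM} px"
        )
    if s == 1.0:
        data = grid.data.copy()
    else:
        data = np.asarray(grid.data, dtype=np.float32)
        # zoom factors chosen to hit the rounded output shape exactly
        data = ndimage.zoom(
            data, (1.0, out_y / y, out_x / x), order=1, mode="nearest", grid_mode=True
        )
        np.clip(data, 0, None, out=data)
    return VoxelGrid3D(
        data=data,
        pixel_size_xy_um=grid.pixel_size_xy_um / s,
        z_step_um=grid.z_step_um,
        channel_name=grid.channel_name,
    )


def compute_anisotropy(z_step_um: float, rescaled_pixel_size_um: float) -> float:
    """Ratio of axial to lateral sampling; > 1 means z is coarser."""
    if not z_step_um > 0:
        raise ValueError("z_step_um must be positive")
    if not rescaled_pixel_size_um > 0:
        raise ValueError("rescaled_pixel_size_um must be positive")
    return z_step_um / rescaled_pixel_size_um


def gaussian_blur(grid: VoxelGrid3D, blurfactor: float, anisotropy: float = 1.0) -> VoxelGrid3D:
    """Physically isotropic 3D Gaussian blur.

    Lateral sigma is ``blurfactor`` pixels; axial sigma is divided by
    *anisotropy* so the kernel is spherical in µm. ``blurfactor == 0``
    returns the grid unchanged. Reflective boundaries conserve total
    intensity away from the borders.
    """
    if blurfactor < 0:
        raise ValueError("blurfactor must be >= 0")
    if not anisotropy > 0:
        raise ValueError("anisotropy must be positive")
    if blurfactor == 0:
        return grid
    data = np.asarray(grid.data, dtype=np.float32)
    sigma = (blurfactor / anisotropy, blurfactor, blurfactor)
    blurred = ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")
    np.clip(blurred, 0, None, out=blurred)
    return VoxelGrid3D(
        data=blurred,
        pixel_size_xy_um=grid.pixel_size_xy_um,
        z_step_um=grid.z_step_um,
        channel_name=grid.channel_name,
    )
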