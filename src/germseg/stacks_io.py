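"""Reading and writing intensity z-stacks and instance label volumes.

All volumes follow the (z, y, x) axis convention with 0-based indices and
TIFF pages mapping to z. Physical calibration travels with the pixels:
``pixel_size_xy_um`` is the lateral sampling (x and y assumed equal, i.e.
square pixels) and ``z_step_um`` the slice spacing. Metadata is resolved
from, in order of precedence, plausible TIFF resolution tags, a sidecar
YAML file, or an explicit :class:`ImageMetadata` argument.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "ImageMetadata",
    "VoxelGrid3D",
    "LabelVolume",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "read_sidecar_metadata",
    "write_sidecar_metadata",
    "sidecar_path",
]

# Resolution tags outside this window (in µm/px) are treated as bogus
# (e.g. default 72 dpi stamps) and ignored in favour of the sidecar.
_PLAUSIBLE_PIXEL_SIZE_UM = (0.01, 10.0)


@dataclasses.dataclass(frozen=True)
class ImageMetadata:
    """Physical calibration of a z-stack.

    Parameters
    ----------
    pixel_size_xy_um : float
        Lateral sampling in µm/pixel (x and y equal).
    z_step_um : float
        Axial spacing between consecutive slices in µm.
    channel_name : str
        Free-text stain/channel label, e.g. ``"DAPI"``.
    """

    pixel_size_xy_um: float
    z_step_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        if not (self.pixel_size_xy_um > 0 and np.isfinite(self.pixel_size_xy_um)):
            raise ValueError(f"pixel_size_xy_um must be positive, got {self.pixel_size_xy_um}")
        if not (self.z_step_um > 0 and np.isfinite(self.z_step_um)):
            raise ValueError(f"z_step_um must be positive, got {self.z_step_um}")


@dataclasses.dataclass
class VoxelGrid3D:
    """An intensity z-stack with physical voxel sizes, axis order (z, y, x)."""

    data: np.ndarray
    pixel_size_xy_um: float
    z_step_um: float
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got shape {self.data.shape}")
        if not (self.pixel_size_xy_um > 0):
            raise ValueError("pixel_size_xy_um must be positive")
        if not (self.z_step_um > 0):
            raise ValueError("z_step_um must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensity values must be finite")
        if np.issubdtype(self.data.dtype, np.floating) and self.data.min() < 0:
            raise ValueError("intensity values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def metadata(self) -> ImageMetadata:
        return ImageMetadata(self.pixel_size_xy_um, self.z_step_um, self.channel_name)

    @property
    def anisotropy(self) -> float:
        """z-step over lateral pixel size; > 1 means z is sampled coarser."""
        return self.z_step_um / self.pixel_size_xy_um


@dataclasses.dataclass
class LabelVolume:
    """Nonnegative-integer instance labels; 0 is background, k > 0 nucleus k.

    Label ids need not be consecutive and are never renumbered by I/O or by
    the post-processing filters.
    """

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) label array, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"labels must be integer-typed, got {self.labels.dtype}")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def instance_ids(self) -> np.ndarray:
        """Sorted array of positive instance ids present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_instances(self) -> int:
        return int(self.instance_ids().size)


def sidecar_path(path: str | Path) -> Path:
    """Path of the YAML metadata sidecar accompanying a TIFF."""
    p = Path(path)
    return p.with_suffix(p.suffix + ".meta.yaml")


def write_sidecar_metadata(path: str | Path, metadata: ImageMetadata) -> Path:
    sp = sidecar_path(path)
    payload = {
        "pixel_size_xy_um": float(metadata.pixel_size_xy_um),
        "z_step_um": float(metadata.z_step_um),
        "channel": metadata.channel_name,
    }
    sp.write_text(yaml.safe_dump(payload, sort_keys=True))
    return sp


def read_sidecar_metadata(path: str | Path) -> ImageMetadata | None:
    """Load the sidecar for *path* if present, else None."""
    sp = sidecar_path(path)
    if not sp.exists():
        return None
    payload = yaml.safe_load(sp.read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"malformed metadata sidecar: {sp}")
    try:
        return ImageMetadata(
            pixel_size_xy_um=float(payload["pixel_size_xy_um"]),
            z_step_um=float(payload["z_step_um"]),
            channel_name=str(payload.get("channel", "")),
        )
    except KeyError as exc:
        raise ValueError(f"metadata sidecar {sp} is missing key {exc}") from exc


def _pixel_size_from_tags(tif: tifffile.TiffFile) -> float | None:
    """Lateral pixel size from TIFF resolution tags, if present and plausible."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return None
    unit_tag = tags.get("ResolutionUnit")
    unit = getattr(unit_tag, "value", None)
    # pixels-per-unit rationals -> µm/px
    to_um = {2: 25400.0, 3: 10000.0}.get(getattr(unit, "value", unit))
    if to_um is None:
        # ImageJ writes unit in its private metadata; assume µm there.
        ij = tif.imagej_metadata or {}
        if ij.get("unit") in ("um", "micron", "µm", "micrometer"):
            to_um = 1.0
        else:
            return None
    sizes = []
    for res in (xres.value, yres.value):
        num, den = (res if isinstance(res, tuple) else (res, 1))
        if not num:
            return None
        sizes.append(to_um * den / num)
    px, py = sizes
    if not np.isclose(px, py, rtol=1e-6):
        raise ValueError(f"non-square pixels in TIFF tags ({px:g} vs {py:g} µm); not supported")
    lo, hi = _PLAUSIBLE_PIXEL_SIZE_UM
    if not (lo <= px <= hi):
        return None
    return float(px)


def _z_step_from_tags(tif: tifffile.TiffFile) -> float | None:
    ij = tif.imagej_metadata or {}
    spacing = ij.get("spacing")
    if spacing is None:
        return None
    spacing = float(spacing)
    lo, hi = _PLAUSIBLE_PIXEL_SIZE_UM
    if not (lo <= spacing <= hi * 10):
        return None
    return spacing


def read_stack(path: str | Path, metadata: ImageMetadata | None = None) -> VoxelGrid3D:
    """Read a single-channel multi-page TIFF as a calibrated z-stack.

    Calibration is taken from plausible TIFF tags first, then the YAML
    sidecar, then the explicit *metadata* argument; a stack with no source
    of calibration is an error. A 2D (single-page) TIFF is accepted and
    promoted to shape (1, H, W).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
        tag_z = _z_step_from_tags(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel z-stack, got array of shape {data.shape}; "
            "select a channel upstream"
        )
    sidecar = read_sidecar_metadata(path)
    fallback = sidecar or metadata
    px = tag_px if tag_px is not None else (fallback.pixel_size_xy_um if fallback else None)
    zs = tag_z if tag_z is not None else (fallback.z_step_um if fallback else None)
    channel = fallback.channel_name if fallback else ""
    if px is None or zs is None:
        raise ValueError(
            f"{path}: no voxel-size metadata found (TIFF tags, sidecar, or explicit argument)"
        )
    return VoxelGrid3D(data=data, pixel_size_xy_um=px, z_step_um=zs, channel_name=channel)


def write_stack(grid: VoxelGrid3D, path: str | Path) -> Path:
    """Write a z-stack as a multi-page TIFF plus a metadata sidecar.

    Integer data round-trips bit-exactly; the sidecar stores voxel sizes at
    full float precision.
    """
    path = Path(path)
    tifffile.imwrite(path, grid.data, photometric="minisblack")
    write_sidecar_metadata(path, grid.metadata)
    return path


def read_labels(path: str | Path) -> LabelVolume:
    """Read an instance label volume from an integer TIFF.

    Float-valued TIFFs are accepted only when every value is an exact
    integer (some writers store labels as float); otherwise an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if np.issubdtype(data.dtype, np.floating):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise ValueError(f"{path}: float TIFF with non-integer values cannot be labels")
        data = rounded.astype(np.int32)
    return LabelVolume(labels=data)


def write_labels(lv: LabelVolume, path: str | Path) -> Path:
    """Write a label volume as an integer multi-page TIFF (lossless)."""
    path = Path(path)
    labels = lv.labels
    if labels.size and labels.max() <= np.iinfo(np.uint16).max:
        labels = labels.astype(np.uint16)
    else:
        labels = labels.astype(np.int32)
    tifffile.imwrite(path, labels, photometric="minisblack")
    return path
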