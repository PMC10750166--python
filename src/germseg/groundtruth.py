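"""Ground-truth preparation: orthogonal views, train/test split, augmentation.

Annotating 2D orthogonal views (xy, xz, yz) of a z-stack is far cheaper than
dense 3D annotation and suffices to train a 2D-view segmentation model.
This module extracts isotropic orthogonal views (xz/yz views are resampled
along z by the anisotropy so one view pixel is one lateral pixel), splits
view collections reproducibly into train and test sets, and applies the
paired image/mask augmentation protocol: random mirroring, random rotations
in [0, 90] degrees, additive noise, intensity rescaling, and blurring with
blur factors in [0, 3.5].

The network-training hyperparameters used with the resulting folders are
recorded in :data:`TRAINING_CONFIG` for provenance only; training itself is
out of scope here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.transform import rotate

from .stacks_io import LabelVolume, VoxelGrid3D

__all__ = [
    "OrthoView",
    "AugmentationSpec",
    "TRAINING_CONFIG",
    "extract_ortho_view",
    "split_train_test",
    "augment_pair",
    "build_training_set",
]

#: Optimizer settings used for retraining the nuclei model; provenance only.
TRAINING_CONFIG: dict = {
    "n_epochs": 500,
    "momentum": 0.9,
    "weight_decay": 1e-05,
    "learning_rate": 0.05,
    "min_train_masks": 2,
    "normalize": True,
    "rescale": True,
}

#: mask fragments below this size (px) after rotation resampling are dropped
_MIN_FRAGMENT_PX = 9

_ORIENTATIONS = ("xy", "xz", "yz")


@dataclasses.dataclass
class OrthoView:
    """A paired 2D intensity slice and label slice from a 3D stack."""

    image: np.ndarray
    mask: np.ndarray
    orientation: str
    source_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image and mask shapes differ: {self.image.shape} vs {self.mask.shape}"
            )
        if self.orientation not in _ORIENTATIONS:
            raise ValueError(f"orientation must be one of {_ORIENTATIONS}")


@dataclasses.dataclass(frozen=True)
class AugmentationSpec:
    """Ranges of the stochastic augmentation transforms.

    Geometric transforms (flips, rotation) hit image and mask identically;
    photometric ones (noise, intensity rescale, blur) hit the image only.
    ``noise_sigma_range`` is relative to the image's standard deviation;
    ``intensity_rescale_range`` is a multiplicative factor; ``blur_range``
    is a Gaussian sigma in pixels, capped at 3.5.
    """

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    rotation_range_deg: tuple[float, float] = (0.0, 90.0)
    noise_sigma_range: tuple[float, float] = (0.0, 0.10)
    intensity_rescale_range: tuple[float, float] = (0.7, 1.3)
    blur_range: tuple[float, float] = (0.0, 3.5)
    n_augment_per_image: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_flip_h, self.p_flip_v):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must be in [0, 1]")
        lo, hi = self.rotation_range_deg
        if not (0 <= lo <= hi <= 90):
            raise ValueError("rotation_range_deg must lie within [0, 90]")
        lo, hi = self.blur_range
        if not (0 <= lo <= hi <= 3.5):
            raise ValueError("blur_range must lie within [0, 3.5]")
        for name in ("noise_sigma_range", "intensity_rescale_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} must be a nondecreasing nonnegative pair")
        if self.n_augment_per_image < 0:
            raise ValueError("n_augment_per_image must be >= 0")


def extract_ortho_view(
    grid: VoxelGrid3D, labels: LabelVolume, orientation: str, index: int
) -> OrthoView:
    """Extract one orthogonal view with its label slice.

    ``xy`` views pass through unchanged. ``xz``/``yz`` views are resampled
    along z by the stack's anisotropy (linear interpolation for intensity,
    nearest for labels) so the view is isotropic at the lateral pixel size.
    """
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    if grid.shape != labels.shape:
        raise ValueError("grid and labels must share a shape")
    nz, ny, nx = grid.shape
    axis_len = {"xy": nz, "xz": ny, "yz": nx}[orientation]
    if not 0 <= index < axis_len:
        raise IndexError(
            f"index {index} out of range for orientation {orientation} (axis length {axis_len})"
        )
    if orientation == "xy":
        img = np.asarray(grid.data[index])
        msk = labels.labels[index]
    else:
        if orientation == "xz":
            img = np.asarray(grid.data[:, index, :], dtype=np.float32)
            msk = labels.labels[:, index, :]
        else:
            img = np.asarray(grid.data[:, :, index], dtype=np.float32)
            msk = labels.labels[:, :, index]
        a = grid.anisotropy
        if not np.isclose(a, 1.0):
            img = ndimage.zoom(img, (a, 1.0), order=1, mode="nearest")
            msk = ndimage.zoom(msk, (a, 1.0), order=0, mode="nearest")
    return OrthoView(
        image=img.copy(),
        mask=np.ascontiguousarray(msk),
        orientation=orientation,
        source_id=f"{orientation}{index:03d}",
    )


def split_train_test(
    items: Sequence, test_fraction: float = 0.1, seed: int = 0
) -> tuple[list, list]:
    """Reproducible random partition into (train, test).

    ``|test| = round(test_fraction * N)``, clipped so neither side is empty;
    e.g. 120 items at fraction 0.1 give 108 train / 12 test.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    n_test = int(round(test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    test_idx = set(order[:n_test].tolist())
    train = [items[i] for i in range(n) if i not in test_idx]
    test = [items[i] for i in range(n) if i in test_idx]
    return train, test


def _relabel_tiny_fragments(mask: np.ndarray) -> np.ndarray:
    """Drop mask fragments below the minimum size created by edge resampling."""
    ids, counts = np.unique(mask, return_counts=True)
    tiny = ids[(ids > 0) & (counts < _MIN_FRAGMENT_PX)]
    if tiny.size:
        mask = mask.copy()
        mask[np.isin(mask, tiny)] = 0
    return mask


def augment_pair(view: OrthoView, spec: AugmentationSpec, rng: np.random.Generator):
    """One stochastic augmentation of an (image, mask) pair.

    Returns (augmented OrthoView, dict of sampled parameters). Geometry
    (flips + rotation, reflective fill, shape preserved) is shared by image
    and mask; noise, intensity rescale and blur touch the image only. The
    mask keeps its integer ids (nearest-neighbor resampling can shrink, but
    never invent, instances).
    """
    img = np.asarray(view.image, dtype=np.float32)
    msk = view.mask
    params = {
        "flip_h": bool(rng.uniform() < spec.p_flip_h),
        "flip_v": bool(rng.uniform() < spec.p_flip_v),
        "rotation_deg": float(rng.uniform(*spec.rotation_range_deg)),
        "noise_sigma_rel": float(rng.uniform(*spec.noise_sigma_range)),
        "intensity_factor": float(rng.uniform(*spec.intensity_rescale_range)),
        "blur_sigma": float(rng.uniform(*spec.blur_range)),
    }
    if params["flip_h"]:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if params["flip_v"]:
        img, msk = img[::-1, :], msk[::-1, :]
    angle = params["rotation_deg"]
    if angle != 0.0:
        img = rotate(img, angle, resize=False, order=1, mode="symmetric", preserve_range=True)
        msk = rotate(
            msk.astype(np.float64), angle, resize=False, order=0, mode="constant",
            cval=0, preserve_range=True,
        ).astype(msk.dtype)
        msk = _relabel_tiny_fragments(msk)

    if params["intensity_factor"] != 1.0:
        lo, hi = float(img.min()), float(img.max())
        img = img * params["intensity_factor"]
        # min-max renormalization back onto the original intensity range
        if img.max() > img.min():
            img = lo + (img - img.min()) * (hi - lo) / (img.max() - img.min())
    if params["blur_sigma"] > 0:
        img = ndimage.gaussian_filter(img, sigma=params["blur_sigma"], mode="reflect")
    if params["noise_sigma_rel"] > 0:
        sd = params["noise_sigma_rel"] * float(np.std(img))
        if sd > 0:
            img = img + rng.normal(0, sd, size=img.shape).astype(np.float32)
    img = np.clip(img, 0, None).astype(np.float32)
    out = OrthoView(image=img, mask=msk, orientation=view.orientation,
                    source_id=view.source_id)
    return out, params


def build_training_set(
    views: Sequence[OrthoView], spec: AugmentationSpec, out_dir: str | Path
) -> pd.DataFrame:
    """Write originals plus augmented variants in Cellpose folder layout.

    For each view, the original and ``spec.n_augment_per_image`` variants
    are saved as ``<stem>_img.tif`` / ``<stem>_masks.tif`` pairs. A CSV
    manifest records every sampled transform parameter plus the training
    hyperparameter provenance, and the whole procedure is reproducible from
    ``spec.seed``: each view gets its own RNG substream keyed on
    (seed, view index), so reordering other views changes nothing.
    """
    if len(views) == 0:
        raise ValueError("no views given")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, view in enumerate(views):
        stem0 = f"view{i:04d}_{view.orientation}_orig"
        tifffile.imwrite(out_dir / f"{stem0}_img.tif", np.asarray(view.image), photometric="minisblack")
        tifffile.imwrite(out_dir / f"{stem0}_masks.tif",
                         np.asarray(view.mask, dtype=np.uint16),
                         photometric="minisblack")
        rows.append({"file_stem": stem0, "view_index": i, "orientation": view.orientation,
                     "source_id": view.source_id, "augmented": False})
        rng = np.random.default_rng([spec.seed, i])
        for j in range(spec.n_augment_per_image):
            aug, params = augment_pair(view, spec, rng)
            stem = f"view{i:04d}_{view.orientation}_aug{j:02d}"
            tifffile.imwrite(out_dir / f"{stem}_img.tif", aug.image, photometric="minisblack")
            tifffile.imwrite(out_dir / f"{stem}_masks.tif",
                             np.asarray(aug.mask, dtype=np.uint16),
                             photometric="minisblack")
            rows.append({"file_stem": stem, "view_index": i,
                         "orientation": view.orientation,
                         "source_id": view.source_id, "augmented": True, **params})
    manifest = pd.DataFrame(rows)
    for key, value in TRAINING_CONFIG.items():
        manifest.attrs[key] = value
    manifest_path = out_dir / "manifest.csv"
    with open(manifest_path, "w") as fh:
        for key, value in TRAINING_CONFIG.items():
            fh.write(f"# training_config {key}={value}\n")
        manifest.to_csv(fh, index=False)
    return manifest
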