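"""Synthetic germline-like z-stacks with exact ground truth.

The generator emulates the distal-germline imaging regime: densely packed
round nuclei of ~3.5 µm diameter whose chromatin staining is discontinuous
(bright foci inside a dimmer nucleoplasm), sampled on an anisotropic voxel
grid (z-step coarser than the xy pixel), blurred by a Gaussian PSF stand-in,
and corrupted by Poisson shot noise plus Gaussian read noise. Ground-truth
labels are the full spheres — the way an annotator outlines whole nuclei —
not the sparse chromatin texture.

Geometry is built in physical µm and rasterized onto the voxel grid, so one
scene description serves any anisotropy.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stacks_io import ImageMetadata, LabelVolume, VoxelGrid3D

__all__ = ["SyntheticSceneSpec", "ScenePlacementError", "generate_scene", "corrupt_labels"]

_MAX_PLACEMENT_TRIES = 10_000


class ScenePlacementError(RuntimeError):
    """Dart-throwing could not place all nuclei at the requested density."""


@dataclasses.dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of one synthetic scene (all sizes in µm).

    Defaults reproduce a typical distal-germline acquisition: 0.117 µm/px
    lateral sampling, 0.3 µm z-step (anisotropy ~2.6), 3.5 µm nuclei with
    ~0.8 µm chromatin foci, a ~0.15 µm-sigma PSF, and moderate shot/read
    noise on a dim background.
    """

    volume_shape_vox: tuple[int, int, int] = (64, 256, 256)
    pixel_size_xy_um: float = 0.117
    z_step_um: float = 0.3
    n_nuclei: int = 20
    diameter_mean_um: float = 3.5
    diameter_sd_um: float = 0.25
    min_gap_um: float = 0.3
    chromatin_n_blobs: int = 14
    chromatin_blob_diameter_um: float = 0.9
    nucleoplasm_level: float = 0.35
    psf_sigma_um: float = 0.15
    noise_gaussian_sd: float = 0.02
    noise_poisson_scale: float = 200.0
    background_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape_vox) != 3 or min(self.volume_shape_vox) < 1:
            raise ValueError("volume_shape_vox must be a (Z, Y, X) triple of positive ints")
        for name in ("pixel_size_xy_um", "z_step_um", "diameter_mean_um",
                     "chromatin_blob_diameter_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("diameter_sd_um", "min_gap_um", "psf_sigma_um",
                     "noise_gaussian_sd", "noise_poisson_scale", "background_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")


def _voxel_sizes(spec: SyntheticSceneSpec) -> np.ndarray:
    return np.array([spec.z_step_um, spec.pixel_size_xy_um, spec.pixel_size_xy_um])


def _place_nuclei(spec: SyntheticSceneSpec, rng: np.random.Generator):
    """Dart-throw sphere centers/radii in physical space, fully interior."""
    vs = _voxel_sizes(spec)
    extent = np.array(spec.volume_shape_vox) * vs
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for _ in range(spec.n_nuclei):
        r = max(0.25 * spec.diameter_mean_um,
                0.5 * (spec.diameter_mean_um + spec.diameter_sd_um * rng.standard_normal()))
        placed = False
        for _try in range(_MAX_PLACEMENT_TRIES):
            # one-voxel pad keeps spheres clear of the stack borders
            lo = r + vs
            hi = extent - r - vs
            if np.any(hi <= lo):
                break
            c = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(c - c2) >= r + r2 + spec.min_gap_um
                for c2, r2 in zip(centers, radii)
            )
            if ok:
                centers.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            vol_frac = (
                sum(4 / 3 * np.pi * rr**3 for rr in radii + [r]) / float(np.prod(extent))
            )
            raise ScenePlacementError(
                f"could not place nucleus {len(centers) + 1}/{spec.n_nuclei} after "
                f"{_MAX_PLACEMENT_TRIES} tries (nuclear volume fraction ~{vol_frac:.2f}); "
                "reduce n_nuclei or enlarge the volume"
            )
    return centers, radii


def _rasterize_ball(shape, vs, center, radius) -> tuple[tuple, np.ndarray]:
    """Voxel mask of a physical ball, restricted to its bounding box."""
    lo_idx = np.maximum(np.floor((center - radius) / vs - 1), 0).astype(int)
    hi_idx = np.minimum(np.ceil((center + radius) / vs + 1), shape).astype(int)
    grids = np.meshgrid(
        *[(np.arange(lo_idx[a], hi_idx[a]) + 0.5) * vs[a] for a in range(3)],
        indexing="ij",
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    box = tuple(slice(lo_idx[a], hi_idx[a]) for a in range(3))
    return box, d2 <= radius**2


def generate_scene(spec: SyntheticSceneSpec) -> tuple[VoxelGrid3D, LabelVolume, ImageMetadata]:
    """Generate one scene: (intensity grid, ground-truth labels, metadata).

    Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape_vox)
    vs = _voxel_sizes(spec)
    centers, radii = _place_nuclei(spec, rng)

    labels = np.zeros(shape, dtype=np.int32)
    signal = np.zeros(shape, dtype=np.float32)
    for k, (c, r) in enumerate(zip(centers, radii), start=1):
        box, ball = _rasterize_ball(shape, vs, c, r)
        labels[box][ball] = k
        # dim nucleoplasm fill so the whole nucleus is above background
        np.maximum(signal[box], spec.nucleoplasm_level * ball, out=signal[box])
        # discontinuous chromatin: bright foci inside the sphere
        for _ in range(spec.chromatin_n_blobs):
            u = rng.standard_normal(3)
            u /= max(np.linalg.norm(u), 1e-12)
            bc = c + u * (0.75 * r) * rng.uniform() ** (1 / 3)
            bbox, bball = _rasterize_ball(shape, vs, bc, spec.chromatin_blob_diameter_um / 2)
            np.maximum(signal[bbox], 1.0 * bball, out=signal[bbox])
    # chromatin stays inside its nucleus
    signal[labels == 0] = 0.0

    if spec.psf_sigma_um > 0:
        from scipy import ndimage

        signal = ndimage.gaussian_filter(signal, sigma=tuple(spec.psf_sigma_um / vs))

    img = signal + spec.background_level
    if spec.noise_poisson_scale > 0:
        img = rng.poisson(img * spec.noise_poisson_scale).astype(np.float32)
        img /= spec.noise_poisson_scale
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0, spec.noise_gaussian_sd, size=shape).astype(np.float32)
    np.clip(img, 0, None, out=img)

    meta = ImageMetadata(spec.pixel_size_xy_um, spec.z_step_um, channel_name="synthetic-DAPI")
    grid = VoxelGrid3D(
        data=img.astype(np.float32),
        pixel_size_xy_um=spec.pixel_size_xy_um,
        z_step_um=spec.z_step_um,
        channel_name=meta.channel_name,
    )
    return grid, LabelVolume(labels=labels), meta


def corrupt_labels(
    lv: LabelVolume, drop_k: int = 0, split_k: int = 0, rng: np.random.Generator | None = None
) -> LabelVolume:
    """Derive a fake prediction with a known error budget from ground truth.

    ``drop_k`` instances are removed (false negatives) and ``split_k``
    instances are bisected into two new ids across a plane through their
    centroid, emulating the fragmentation failure mode of generic models on
    germline nuclei. Each fragment is kept strictly below 0.5 IoU with its
    parent (for odd voxel counts one mid-plane voxel is deleted so neither
    half exceeds half the parent volume), so TP/FP/FN against the original
    — hence the Jaccard index — is exactly predictable: drop adds one FN,
    split adds one FN and two FP.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    ids = lv.instance_ids()
    if drop_k + split_k > ids.size:
        raise ValueError(
            f"cannot drop {drop_k} and split {split_k} of {ids.size} instances"
        )
    out = lv.labels.copy()
    chosen = rng.choice(ids, size=drop_k + split_k, replace=False)
    drop_ids, split_ids = chosen[:drop_k], chosen[drop_k:]
    if drop_ids.size:
        out[np.isin(out, drop_ids)] = 0
    next_id = int(lv.labels.max()) + 1
    for sid in split_ids:
        coords = np.argwhere(out == sid)
        extents = coords.max(axis=0) - coords.min(axis=0)
        axis = int(np.argmax(extents))
        order = np.lexsort(
            [coords[:, a] for a in range(3) if a != axis] + [coords[:, axis]]
        )
        coords = coords[order]
        n = len(coords)
        half = n // 2
        a, b = coords[:half], coords[half:]
        if n % 2 == 1:  # delete the mid-plane voxel: both halves < n/2
            b = b[1:]
            out[tuple(coords[half])] = 0
        out[tuple(a.T)] = next_id
        out[tuple(b.T)] = next_id + 1
        next_id += 2
    return LabelVolume(labels=out)
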