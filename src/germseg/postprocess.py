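"""Post-segmentation filters: border clearing and shape/size criteria.

Both operations only ever delete whole instances — surviving voxel sets and
label ids are untouched, so downstream quantification sees exactly the
backend's geometry.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.measure import regionprops

from .stacks_io import LabelVolume

__all__ = ["FilterCriteria", "clean_borders", "filter_masks", "measure_instances"]

#: lateral margin of the border-clearing rule, in pixels
BORDER_MARGIN_XY = 2


@dataclasses.dataclass(frozen=True)
class FilterCriteria:
    """Per-instance acceptance bounds; every criterion is optional (None = off).

    size bounds are voxel counts; ``min_solidity`` is volume over 3D
    convex-hull volume; ``max_elongation`` bounds the ratio of largest to
    smallest principal-axis length measured in physical µm (z scaled by the
    z-step so anisotropy does not masquerade as shape); ``min_z_thickness``
    is the number of distinct z slices an instance occupies.
    """

    min_size_vox: int | None = None
    max_size_vox: int | None = None
    min_solidity: float | None = None
    max_elongation: float | None = None
    min_z_thickness: int | None = None

    def __post_init__(self) -> None:
        for name in ("min_size_vox", "max_size_vox", "min_solidity", "min_z_thickness"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.max_elongation is not None and self.max_elongation < 1:
            raise ValueError("max_elongation must be >= 1 (it is a ratio of axis lengths)")
        if (
            self.min_size_vox is not None
            and self.max_size_vox is not None
            and self.min_size_vox > self.max_size_vox
        ):
            raise ValueError("min_size_vox must not exceed max_size_vox")

    @property
    def is_empty(self) -> bool:
        return all(
            getattr(self, f.name) is None for f in dataclasses.fields(self)
        )


def clean_borders(lv: LabelVolume) -> LabelVolume:
    """Delete incomplete nuclei at the stack borders.

    An instance is removed iff it has a voxel on the first or last z slice,
    or any voxel within 2 pixels of the lateral edges (index < 2 or
    >= dim - 2 in y or x). Survivors keep their ids. Idempotent.
    """
    labels = lv.labels
    nz, ny, nx = labels.shape
    m = BORDER_MARGIN_XY
    border_ids = np.concatenate(
        [
            labels[0].ravel(),
            labels[-1].ravel(),
            labels[:, :m, :].ravel(),
            labels[:, max(ny - m, 0):, :].ravel(),
            labels[:, :, :m].ravel(),
            labels[:, :, max(nx - m, 0):].ravel(),
        ]
    )
    border_ids = np.unique(border_ids)
    border_ids = border_ids[border_ids > 0]
    if border_ids.size == 0:
        return LabelVolume(labels=labels.copy())
    out = labels.copy()
    out[np.isin(out, border_ids)] = 0
    return LabelVolume(labels=out)


def measure_instances(
    lv: LabelVolume, pixel_size_xy_um: float = 1.0, z_step_um: float = 1.0
):
    """Per-instance measurements used by :func:`filter_masks`.

    Returns a list of dicts with keys label, size_vox, solidity, elongation,
    z_thickness. Elongation is the ratio of the largest to smallest
    principal-axis length of the voxel cloud in physical coordinates;
    degenerate instances (single voxel, or zero extent along an axis after
    the half-voxel regularization) fall back to the stated conventions.
    """
    out = []
    for rp in regionprops(lv.labels):
        size = int(rp.area)
        coords = rp.coords
        z_thickness = int(np.unique(coords[:, 0]).size)
        if size == 1:
            out.append(
                {"label": int(rp.label), "size_vox": 1, "solidity": 1.0,
                 "elongation": 1.0, "z_thickness": 1}
            )
            continue
        if np.any(coords.max(axis=0) == coords.min(axis=0)):
            solidity = 1.0  # coplanar/collinear voxels have no 3D hull
        else:
            try:
                with np.errstate(divide="ignore", invalid="ignore"):
                    solidity = float(rp.solidity)
            except Exception:  # Qhull degeneracy
                solidity = 1.0
            if not np.isfinite(solidity):
                solidity = 1.0
        phys = coords.astype(np.float64) * np.array([z_step_um, pixel_size_xy_um, pixel_size_xy_um])
        cov = np.cov(phys, rowvar=False)
        # half-voxel variance floor so flat objects get a finite thickness
        cov += np.diag([z_step_um, pixel_size_xy_um, pixel_size_xy_um]) ** 2 / 12.0
        ev = np.linalg.eigvalsh(cov)
        elongation = float(np.sqrt(ev[-1] / ev[0]))
        out.append(
            {
                "label": int(rp.label),
                "size_vox": size,
                "solidity": solidity,
                "elongation": elongation,
                "z_thickness": z_thickness,
            }
        )
    return out


def filter_masks(
    lv: LabelVolume,
    criteria: FilterCriteria,
    pixel_size_xy_um: float = 1.0,
    z_step_um: float = 1.0,
) -> LabelVolume:
    """Keep an instance iff it satisfies every active criterion."""
    if criteria.is_empty:
        return LabelVolume(labels=lv.labels.copy())
    drop: list[int] = []
    for m in measure_instances(lv, pixel_size_xy_um, z_step_um):
        ok = True
        if criteria.min_size_vox is not None and m["size_vox"] < criteria.min_size_vox:
            ok = False
        if criteria.max_size_vox is not None and m["size_vox"] > criteria.max_size_vox:
            ok = False
        if criteria.min_solidity is not None and m["solidity"] < criteria.min_solidity:
            ok = False
        if criteria.max_elongation is not None and m["elongation"] > criteria.max_elongation:
            ok = False
        if criteria.min_z_thickness is not None and m["z_thickness"] < criteria.min_z_thickness:
            ok = False
        if not ok:
            drop.append(m["label"])
    out = lv.labels.copy()
    if drop:
        out[np.isin(out, drop)] = 0
    return LabelVolume(labels=out)
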