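"""End-to-end segmentation pipeline.

Composes the stages in the order the plugin applies them: lateral rescale
to a 30 px nucleus diameter -> Gaussian blur -> 3D backend segmentation
with metadata-derived anisotropy -> map labels back onto the original voxel
grid -> optional border clearing -> optional shape/size filters. Every
resolved parameter is logged so runs are auditable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from . import backends, postprocess, preprocess
from .postprocess import FilterCriteria
from .stacks_io import ImageMetadata, LabelVolume, VoxelGrid3D

__all__ = ["SegmentationParams", "run_pipeline"]

logger = logging.getLogger("germseg.pipeline")


@dataclasses.dataclass(frozen=True)
class SegmentationParams:
    """User-facing knobs of the whole pipeline (plugin defaults)."""

    diameter_um: float = 3.5
    blurfactor: float = 2.5
    cellprob_threshold: float = 0.0
    clean_borders: bool = False
    filter_criteria: FilterCriteria = dataclasses.field(default_factory=FilterCriteria)
    backend: str = "baseline"
    backend_kwargs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if self.blurfactor < 0:
            raise ValueError("blurfactor must be >= 0")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    grid: VoxelGrid3D,
    metadata: ImageMetadata | None = None,
    params: SegmentationParams | None = None,
) -> LabelVolume:
    """Segment a calibrated z-stack; labels come back on the original grid.

    *metadata* overrides the calibration carried by *grid* when given.
    The output label volume has exactly the input shape: the backend runs
    at the rescaled resolution and its instance map is resampled back by
    nearest-neighbor.
    """
    params = params or SegmentationParams()
    if metadata is not None:
        grid = VoxelGrid3D(
            data=grid.data,
            pixel_size_xy_um=metadata.pixel_size_xy_um,
            z_step_um=metadata.z_step_um,
            channel_name=metadata.channel_name or grid.channel_name,
        )
    original_shape = grid.shape

    s = _stage("rescale")(preprocess.compute_scale_factor)(
        grid.pixel_size_xy_um, params.diameter_um
    )
    rescaled = _stage("rescale")(preprocess.rescale_xy)(grid, s)
    anisotropy = preprocess.compute_anisotropy(
        rescaled.z_step_um, rescaled.pixel_size_xy_um
    )
    logger.info(
        "scale_factor=%.4f rescaled_pixel_size_um=%.5f anisotropy=%.3f "
        "blurfactor=%.2f cellprob_threshold=%.2f backend=%s clean_borders=%s",
        s, rescaled.pixel_size_xy_um, anisotropy, params.blurfactor,
        params.cellprob_threshold, params.backend, params.clean_borders,
    )

    blurred = _stage("blur")(preprocess.gaussian_blur)(
        rescaled, params.blurfactor, anisotropy
    )

    request = backends.BackendRequest(
        grid=blurred, anisotropy=anisotropy,
        cellprob_threshold=params.cellprob_threshold,
    )
    seg = _stage("segment")(backends.segment)(
        request, backend=params.backend, **params.backend_kwargs
    )

    labels = seg.labels
    if labels.shape != original_shape:
        zoom = [o / c for o, c in zip(original_shape, labels.shape)]
        labels = _stage("resample-back")(ndimage.zoom)(
            labels, zoom, order=0, mode="nearest", grid_mode=True
        )
        labels = np.ascontiguousarray(labels[: original_shape[0],
                                             : original_shape[1],
                                             : original_shape[2]])
    result = LabelVolume(labels=labels.astype(np.int32))
    logger.info("backend produced %d instances", result.n_instances)

    if params.clean_borders:
        result = _stage("clean_borders")(postprocess.clean_borders)(result)
        logger.info("after clean_borders: %d instances", result.n_instances)
    if not params.filter_criteria.is_empty:
        result = _stage("filter_masks")(postprocess.filter_masks)(
            result, params.filter_criteria,
            pixel_size_xy_um=grid.pixel_size_xy_um, z_step_um=grid.z_step_um,
        )
        logger.info("after filter_masks: %d instances", result.n_instances)
    return result
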