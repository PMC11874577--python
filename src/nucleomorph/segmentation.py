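"""Post-processing of binary segmentation output into nucleus instances.

The deep segmentation model upstream of this module emits binary masks; the
pipeline here is connected-component labeling followed by removal of objects
smaller than a minimum plausible nuclear area (default 7 µm², chosen to
exclude fragments that are not complete, valid nuclei).  A classical
threshold-plus-watershed segmenter is provided as a stand-in front end for
end-to-end demonstrations on synthetic images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, measure, segmentation as skseg

from nucleomorph.core_io import Calibration, LabelMask

__all__ = ["SegmentationConfig", "label_components", "filter_small", "baseline_segment"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Instance post-processing parameters.

    ``min_area_um2`` — instances strictly smaller than this are discarded
    (default 7.0 µm²).  ``connectivity`` — 4- or 8-neighbor foreground
    connectivity (default 8).  ``border_policy`` — whether instances
    touching the image border are kept (default) or dropped; the manual
    grid protocol excludes border-cut nuclei, the algorithmic path keeps
    them.
    """

    min_area_um2: float = 7.0
    connectivity: int = 8
    border_policy: str = "keep"

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0:
            raise ValueError("min_area_um2 must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")


def _border_ids(labels: np.ndarray) -> np.ndarray:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    edge = np.unique(edge)
    return edge[edge > 0]


def label_components(binary_mask: np.ndarray | LabelMask, config: SegmentationConfig | None = None,
                     calibration: Calibration | None = None) -> LabelMask:
    """Label maximal connected foreground components of a binary mask.

    Components are numbered 1..K in raster-scan order of their first pixel.
    Rejects masks that already carry instance labels (use
    :func:`nucleomorph.core_io.read_label_mask` for those).
    """
    config = config or SegmentationConfig()
    if isinstance(binary_mask, LabelMask):
        calibration = calibration or binary_mask.calibration
        arr = binary_mask.labels
    else:
        arr = np.asarray(binary_mask)
    calibration = calibration or Calibration()
    values = np.unique(arr)
    if not np.isin(values, [0, 1]).all():
        raise ValueError(
            "label_components expects a binary {0,1} mask; for an instance "
            "label image use read_label_mask / LabelMask directly"
        )
    structure = (
        np.ones((3, 3), dtype=int)
        if config.connectivity == 8
        else np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    labels, _ = ndimage.label(arr, structure=structure)
    mask = LabelMask(labels, calibration)
    if config.border_policy == "drop":
        drop = _border_ids(labels)
        if drop.size:
            out = labels.copy()
            out[np.isin(out, drop)] = 0
            mask = LabelMask(out, calibration)
            mask = _relabel_contiguous(mask)
    return mask


def _relabel_contiguous(mask: LabelMask) -> LabelMask:
    ids = mask.instance_ids
    lut = np.zeros(int(mask.labels.max(initial=0)) + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1)
    return LabelMask(lut[mask.labels], mask.calibration)


def filter_small(
    mask: LabelMask, config: SegmentationConfig | None = None
) -> tuple[LabelMask, int]:
    """Remove instances with area strictly below ``min_area_um2``.

    Returns the filtered mask (labels re-indexed contiguously, preserving
    raster order) and the number of removed instances.  Idempotent.
    """
    config = config or SegmentationConfig()
    areas = mask.instance_areas_um2()
    drop = [i for i, a in areas.items() if a < config.min_area_um2]
    if not drop:
        return _relabel_contiguous(mask), 0
    out = mask.labels.copy()
    out[np.isin(out, drop)] = 0
    return _relabel_contiguous(LabelMask(out, mask.calibration)), len(drop)


def baseline_segment(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    calibration: Calibration | None = None,
    *,
    min_distance_px: int | None = None,
) -> LabelMask:
    """Classical segmenter for darker-than-background nuclei.

    Otsu global threshold -> hole filling -> distance-transform watershed to
    split touching nuclei -> component labeling -> small-object filter.
    Deterministic for a fixed input.  This is a conventional front end for
    demonstrations and synthetic images, not a replacement for a trained
    segmentation model.
    """
    config = config or SegmentationConfig()
    calibration = calibration or Calibration()
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if np.ptp(img) == 0:
        warnings.warn("uniform image: no nuclei found")
        return LabelMask(np.zeros(img.shape, dtype=np.int32), calibration)
    thresh = filters.threshold_otsu(img)
    fg = ndimage.binary_fill_holes(img < thresh)
    if not fg.any():
        warnings.warn("threshold yielded empty foreground")
        return LabelMask(np.zeros(img.shape, dtype=np.int32), calibration)

    distance = ndimage.distance_transform_edt(fg)
    if min_distance_px is None:
        # a nucleus of min_area_um2 has radius sqrt(A/pi); never below 3 px
        r_min = np.sqrt(config.min_area_um2 / np.pi) / calibration.microns_per_pixel
        min_distance_px = max(3, int(round(r_min)))
    from skimage.feature import peak_local_max

    peaks = peak_local_max(
        distance, min_distance=min_distance_px, labels=fg, exclude_border=False
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    ws = skseg.watershed(-distance, markers, mask=fg)

    # watershed labels are already instances; renumber in raster order
    binary_conn = 2 if config.connectivity == 8 else 1
    relabeled = measure.label(ws, background=0, connectivity=binary_conn)
    mask = LabelMask(relabeled.astype(np.int32), calibration)
    if config.border_policy == "drop":
        drop = _border_ids(mask.labels)
        out = mask.labels.copy()
        out[np.isin(out, drop)] = 0
        mask = LabelMask(out, calibration)
    filtered, _ = filter_small(mask, config)
    return filtered
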