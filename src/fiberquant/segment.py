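"""Laminin-based myofiber segmentation and fixed-threshold area measures.

The fiber pipeline follows the threshold-invert-repair recipe used for
quantitative MyHC immunohistology: the laminin image is thresholded to a
boundary mask, broken contour lines are repaired morphologically
(shrinking each enclosed area into a closed object and expanding it back
to its original size, implemented as closing of the boundary mask with a
disk), the mask is inverted, and connected interior regions become the
segmented myofibers after size filtering and removal of objects cut by
the image border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk
from skimage.segmentation import clear_border

from .exceptions import DegenerateSegmentationError
from .section import FiberLabelMap

__all__ = [
    "SegmentationParams",
    "segment_fibers",
    "fiber_csa",
    "segment_nuclei",
    "positive_area_fraction",
    "match_label_maps",
]


@dataclass
class SegmentationParams:
    """Knobs of the fiber segmentation pipeline.

    threshold_method
        ``"otsu"`` or ``"fixed"``; fixed thresholds require
        ``threshold_value`` (the collagen-style convention of one value
        applied to all images).
    closing_radius
        Disk radius (px) of the boundary gap-repair step. Gaps narrower
        than roughly twice the radius are sealed; intact objects keep
        their original size. 0 disables the repair.
    min_fiber_area_um2, max_fiber_area_um2
        Size filter; defaults bracket the usual TA fiber CSA range.
    smoothing_sigma
        Optional Gaussian pre-smoothing of the laminin image (px).
    """

    threshold_method: str = "otsu"
    threshold_value: float | None = None
    closing_radius: int = 4
    min_fiber_area_um2: float = 200.0
    max_fiber_area_um2: float = 8000.0
    smoothing_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed thresholding requires threshold_value")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be >= 0")
        if not 0 < self.min_fiber_area_um2 < self.max_fiber_area_um2:
            raise ValueError("need 0 < min_fiber_area_um2 < max_fiber_area_um2")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def _threshold(img: np.ndarray, params: SegmentationParams) -> tuple[np.ndarray, float]:
    if params.threshold_method == "fixed":
        t = float(params.threshold_value)
    else:
        if img.min() == img.max():
            raise DegenerateSegmentationError(
                "uniform-intensity image: no threshold separates boundary from tissue",
                threshold=float(img.min()),
            )
        t = float(threshold_otsu(img))
    mask = img >= t
    if mask.all() or not mask.any():
        raise DegenerateSegmentationError(
            f"threshold {t:g} produced an all-"
            f"{'foreground' if mask.all() else 'background'} mask",
            threshold=t,
        )
    return mask, t


def segment_fibers(
    laminin: np.ndarray,
    params: SegmentationParams | None = None,
    pixel_size_um: float = 1.0,
) -> FiberLabelMap:
    """Segment myofibers from a laminin immunofluorescence raster.

    Pipeline: optional Gaussian smoothing -> threshold -> boundary mask ->
    morphological closing of the boundary (gap repair) -> invert ->
    4-connected component labeling -> area filter -> removal of
    border-touching fibers -> consecutive relabeling.

    Raises
    ------
    DegenerateSegmentationError
        If thresholding yields an all-foreground or all-background mask;
        the error names the threshold that was applied.
    """
    params = params or SegmentationParams()
    img = np.asarray(laminin, dtype=float)
    if img.size == 0:
        raise ValueError("empty laminin raster")
    if params.smoothing_sigma > 0:
        img = gaussian(img, sigma=params.smoothing_sigma, preserve_range=True)
    boundary, _ = _threshold(img, params)
    if params.closing_radius > 0:
        boundary = closing(boundary, footprint=disk(params.closing_radius))
    interior = ~boundary
    # 4-connectivity so interiors cannot leak diagonally through a 1-px gap
    labels = cc_label(interior, connectivity=1)

    areas_px = np.bincount(labels.ravel())
    px_area = pixel_size_um**2
    lo = params.min_fiber_area_um2 / px_area
    hi = params.max_fiber_area_um2 / px_area
    keep = (areas_px >= lo) & (areas_px <= hi)
    keep[0] = False
    labels = np.where(keep[labels], labels, 0)
    labels = clear_border(labels)
    # relabel consecutively, preserving scan order
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return FiberLabelMap(labels=lut[labels], pixel_size_um=pixel_size_um)


def fiber_csa(label_map: FiberLabelMap) -> pd.DataFrame:
    """Per-fiber cross-sectional area: pixel count x pixel_size_um^2."""
    ids = label_map.fiber_ids
    if ids.size == 0:
        return pd.DataFrame({"fiber_id": [], "csa_um2": []}).astype(
            {"fiber_id": np.int32, "csa_um2": float}
        )
    counts = np.bincount(label_map.labels.ravel())[ids]
    return pd.DataFrame(
        {"fiber_id": ids.astype(np.int32), "csa_um2": counts * label_map.pixel_size_um**2}
    )


def segment_nuclei(
    dapi: np.ndarray,
    min_area_um2: float = 9.0,
    pixel_size_um: float = 1.0,
    threshold_value: float | None = None,
) -> FiberLabelMap:
    """Segment nuclei from a DAPI raster.

    Otsu threshold (or a fixed value) -> fill holes -> drop components
    smaller than ``min_area_um2`` -> label. Touching nuclei are not split;
    they count as one object.
    """
    img = np.asarray(dapi, dtype=float)
    if img.size == 0:
        raise ValueError("empty DAPI raster")
    params = SegmentationParams(
        threshold_method="otsu" if threshold_value is None else "fixed",
        threshold_value=threshold_value,
    )
    mask, _ = _threshold(img, params)
    mask = ndimage.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)
    areas_px = np.bincount(labels.ravel())
    keep = areas_px >= min_area_um2 / pixel_size_um**2
    keep[0] = False
    labels = np.where(keep[labels], labels, 0)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return FiberLabelMap(labels=lut[labels], pixel_size_um=pixel_size_um)


def positive_area_fraction(channel: np.ndarray, fixed_threshold: float) -> float:
    """Percent of field pixels at or above a fixed intensity threshold.

    This is the collagen quantification convention: one threshold applied
    to all images, percent positive area of the total field.
    """
    img = np.asarray(channel)
    if img.size == 0:
        raise ValueError("empty raster")
    return 100.0 * np.count_nonzero(img >= fixed_threshold) / img.size


# ---------------------------------------------------------------------------
# Label-map matching (evaluation against ground truth)
# ---------------------------------------------------------------------------

def _touches_border(labels: np.ndarray) -> np.ndarray:
    """Boolean mask over label ids (index = id) that touch the raster edge."""
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    out = np.zeros(labels.max() + 1, dtype=bool)
    out[np.unique(edge)] = True
    out[0] = False
    return out


def match_label_maps(
    truth: FiberLabelMap,
    predicted: FiberLabelMap,
    iou_threshold: float = 0.8,
    exclude_border_truth: bool = True,
    truth_area_range_um2: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """One-to-one matching of ground-truth fibers to predicted fibers.

    For every eligible truth fiber the best-overlapping predicted fiber is
    found and the pair is accepted when its intersection-over-union meets
    ``iou_threshold`` and the predicted fiber is not claimed twice
    (greedy, by descending IoU; above IoU 0.5 the match is unique anyway).

    Returns a frame with columns ``truth_id``, ``pred_id`` (0 = unmatched)
    and ``iou``; truth fibers touching the border (censored by the
    segmentation contract) and outside ``truth_area_range_um2`` are
    excluded from the frame.
    """
    t = truth.labels.ravel()
    p = predicted.labels.ravel()
    if t.shape != p.shape:
        raise ValueError("label maps differ in shape")
    n_t, n_p = truth.labels.max() + 1, predicted.labels.max() + 1
    contingency = sparse.coo_matrix(
        (np.ones(t.size, dtype=np.int64), (t, p)), shape=(n_t, n_p)
    ).tocsr()
    t_areas = np.bincount(t, minlength=n_t)
    p_areas = np.bincount(p, minlength=n_p)

    eligible = np.ones(n_t, dtype=bool)
    eligible[0] = False
    if exclude_border_truth:
        eligible &= ~_touches_border(truth.labels)
    if truth_area_range_um2 is not None:
        lo, hi = truth_area_range_um2
        areas_um2 = t_areas * truth.pixel_size_um**2
        eligible &= (areas_um2 >= lo) & (areas_um2 <= hi)

    candidates = []
    for tid in np.flatnonzero(eligible):
        row = contingency.getrow(tid)
        for pid, inter in zip(row.indices, row.data):
            if pid == 0:
                continue
            iou = inter / (t_areas[tid] + p_areas[pid] - inter)
            candidates.append((iou, tid, pid))
    candidates.sort(reverse=True)

    best_iou = np.zeros(n_t)
    best_pid = np.zeros(n_t, dtype=np.int64)
    used_p: set[int] = set()
    for iou, tid, pid in candidates:
        if best_pid[tid] != 0 or pid in used_p or iou < iou_threshold:
            continue
        best_pid[tid] = pid
        best_iou[tid] = iou
        used_p.add(pid)

    tids = np.flatnonzero(eligible)
    return pd.DataFrame(
        {"truth_id": tids, "pred_id": best_pid[tids], "iou": best_iou[tids]}
    )
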