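"""Nucleus segmentation from the DAPI channel.

Smoothed-Otsu thresholding, hole filling, optional watershed splitting of
touching nuclei seeded at distance-transform maxima, and an area filter.
The downstream statistic depends only on per-nucleus mean intensities, so a
simple, deterministic pipeline is preferred over anything learned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

__all__ = ["SegmentationParams", "segment_nuclei", "match_to_truth"]

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    threshold_method: str = "otsu"  # "otsu" or "fixed"
    fixed_threshold: float = 0.0
    min_area: int = 50
    max_area: int = 5000
    split_touching: bool = True
    smoothing_sigma: float = 2.0

    def validate(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if not (0 < self.min_area < self.max_area):
            raise ValueError(
                f"require 0 < min_area < max_area, got {self.min_area}, {self.max_area}"
            )
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


def segment_nuclei(dapi_image: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment nuclei in a single-channel DAPI image into a label mask.

    Returns an int32 mask with background 0 and consecutive positive labels.
    A constant image under Otsu thresholding yields an empty mask (with a
    warning) rather than an error.
    """
    if params is None:
        params = SegmentationParams()
    params.validate()
    img = np.asarray(dapi_image)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")

    smoothed = gaussian(img.astype(float), sigma=params.smoothing_sigma, preserve_range=True)
    if params.threshold_method == "otsu":
        if np.ptp(smoothed) == 0:
            logger.warning("constant image: Otsu threshold undefined, returning empty mask")
            return np.zeros(img.shape, dtype=np.int32)
        thr = threshold_otsu(smoothed)
    else:
        thr = params.fixed_threshold
    fg = smoothed > thr
    fg = ndi.binary_fill_holes(fg)

    if params.split_touching and fg.any():
        distance = ndi.distance_transform_edt(fg)
        # seed separation ~ diameter of the smallest admissible nucleus, so
        # EDT plateau pixels inside one nucleus collapse to a single seed
        min_dist = max(3, int(round(2 * math.sqrt(params.min_area / math.pi))))
        coords = peak_local_max(
            distance, min_distance=min_dist, labels=cc_label(fg, connectivity=2),
            exclude_border=False,
        )
        markers = np.zeros(fg.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = watershed(-distance, markers, mask=fg, connectivity=2)
    else:
        labels = cc_label(fg, connectivity=2).astype(np.int32)

    areas = np.bincount(labels.ravel())
    bad = np.flatnonzero((areas < params.min_area) | (areas > params.max_area))
    labels[np.isin(labels, bad[bad > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def match_to_truth(label_mask: np.ndarray, truth_mask: np.ndarray) -> pd.DataFrame:
    """Greedy one-to-one matching of predicted to ground-truth objects by IoU.

    Returns a table with nullable-integer columns ``pred_id`` and
    ``truth_id``, the pair's ``iou`` and a ``matched`` flag; pairs below IoU
    0.5 and leftover objects on either side appear as unmatched rows (missing
    partner id, iou of the best overlap or 0).
    """
    pred = np.asarray(label_mask)
    truth = np.asarray(truth_mask)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")

    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]

    pred_areas = dict(zip(*np.unique(pred[pred > 0], return_counts=True))) if pred_ids.size else {}
    truth_areas = dict(zip(*np.unique(truth[truth > 0], return_counts=True))) if truth_ids.size else {}

    # joint histogram over overlapping foreground pixels
    both = (pred > 0) & (truth > 0)
    pairs: list[tuple[float, int, int]] = []
    if both.any():
        p, t = pred[both].astype(np.int64), truth[both].astype(np.int64)
        key = p * (truth.max() + 1) + t
        uniq, counts = np.unique(key, return_counts=True)
        for k, inter in zip(uniq, counts):
            pi, ti = divmod(int(k), int(truth.max() + 1))
            union = pred_areas[pi] + truth_areas[ti] - inter
            pairs.append((inter / union, pi, ti))

    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    rows = []
    for iou, pi, ti in pairs:
        if pi in used_pred or ti in used_truth:
            continue
        if iou >= 0.5:
            used_pred.add(pi)
            used_truth.add(ti)
            rows.append((pi, ti, iou, True))
    best_iou_pred = {pi: max((i for i, p, _ in pairs if p == pi), default=0.0) for pi in pred_ids}
    best_iou_truth = {ti: max((i for i, _, t in pairs if t == ti), default=0.0) for ti in truth_ids}
    for pi in pred_ids:
        if int(pi) not in used_pred:
            rows.append((int(pi), None, best_iou_pred[pi], False))
    for ti in truth_ids:
        if int(ti) not in used_truth:
            rows.append((None, int(ti), best_iou_truth[ti], False))

    df = pd.DataFrame(rows, columns=["pred_id", "truth_id", "iou", "matched"])
    df["pred_id"] = df["pred_id"].astype("Int64")
    df["truth_id"] = df["truth_id"].astype("Int64")
    return df.sort_values(["matched", "iou"], ascending=[False, False]).reset_index(drop=True)
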