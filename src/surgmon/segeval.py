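"""Segmentation post-processing and IoU-based scoring.

The segmenter emits per-pixel certainty maps in [0, 1] for each class
(cornea, forceps tips, incisional site). Maps are binarized at 0.5,
scored against ground truth with IoU = |overlap| / |union|, and summarized
as detection rates ACC_{IoU>=N} — the fraction of frames whose IoU meets
threshold N — over a grid of N. For visualization each 8-connected
component of a binarized map gets its minimum enclosing circle, and
certainty maps can be rendered as a blue (0) to red (1) gradation
blended over the frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .phantom import MaskSet

DEFAULT_N_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1))


@dataclass
class CircleAnnotation:
    """Minimum enclosing circle of one detected object."""

    center: tuple[float, float]    # (x, y) pixel coordinates
    radius: float
    cls: str = ""


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection-over-union of two binary masks.

    The degenerate both-empty case is defined as 1.0: an empty prediction
    of an absent object is a correct prediction.
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must share one shape")
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


def acc_iou_ge(ious, n: float) -> float:
    """Fraction of frames whose IoU meets or exceeds N (the detection rate)."""
    ious = np.asarray(ious, dtype=np.float64)
    if ious.size == 0:
        raise ValueError("need at least one IoU value")
    if not 0.0 <= n <= 1.0:
        raise ValueError("N must lie in [0, 1]")
    return float((ious >= n).mean())


def binarize(certainty: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixelwise certainty >= threshold -> 1 else 0."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    c = np.asarray(certainty, dtype=np.float64)
    if c.min() < -1e-9 or c.max() > 1 + 1e-9:
        raise ValueError("certainty values must lie in [0, 1]")
    return (c >= threshold).astype(np.uint8)


def _min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Welzl's algorithm (iterative, move-to-front) on (x, y) points."""
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) > 64:
        # the minimum circle touches only hull points
        from scipy.spatial import ConvexHull, QhullError
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points — use them all

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.linalg.norm(a - c))

    def circle_three(a, b, c):
        ax, ay = a; bx, by = b; cx, cy = c
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if abs(d) < 1e-12:
            # collinear: take the widest pair
            best = None
            for p, q in ((a, b), (a, c), (b, c)):
                cen, r = circle_two(p, q)
                if best is None or r > best[1]:
                    best = (cen, r)
            return best
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
              + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
              + (cx**2 + cy**2) * (bx - ax)) / d
        cen = np.array([ux, uy])
        return cen, float(np.linalg.norm(a - cen))

    def contains(cen, r, p):
        return np.linalg.norm(p - cen) <= r + 1e-9

    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]
    cen, r = pts[0], 0.0
    for i in range(1, len(pts)):
        if contains(cen, r, pts[i]):
            continue
        cen, r = pts[i], 0.0
        for j in range(i):
            if contains(cen, r, pts[j]):
                continue
            cen, r = circle_two(pts[i], pts[j])
            for k in range(j):
                if contains(cen, r, pts[k]):
                    continue
                cen, r = circle_three(pts[i], pts[j], pts[k])
    return cen, r


def circumscribed_circles(mask: np.ndarray, cls: str = "",
                          pad: float = 0.5) -> list[CircleAnnotation]:
    """One minimum enclosing circle per 8-connected component of a binary mask.

    The radius is padded by half a pixel so the whole pixel square of every
    component member is enclosed; an empty mask yields an empty list.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    labels = cc_label(mask, connectivity=2)
    out: list[CircleAnnotation] = []
    for lab in range(1, labels.max() + 1):
        ys, xs = np.nonzero(labels == lab)
        cen, r = _min_enclosing_circle(np.column_stack([xs, ys]).astype(float))
        out.append(CircleAnnotation((float(cen[0]), float(cen[1])), r + pad, cls))
    return out


def gradation_overlay(frame: np.ndarray, certainty: np.ndarray,
                      alpha: float = 0.5) -> np.ndarray:
    """Blend a blue (certainty 0) to red (certainty 1) map over an RGB frame."""
    c = np.asarray(certainty, dtype=np.float64)
    if c.shape != frame.shape[:2]:
        raise ValueError("certainty map and frame must share spatial dims")
    tint = np.stack([c, np.zeros_like(c), 1.0 - c], axis=-1) * 255.0
    base = np.asarray(frame, dtype=np.float64)
    return np.clip((1 - alpha) * base + alpha * tint, 0, 255).astype(np.uint8)


@dataclass
class IoUSummary:
    """Per-frame IoU values and the ACC_{IoU>=N} detection-rate table."""

    per_frame: pd.DataFrame        # columns: frame, class, iou, truth_empty
    acc_table: pd.DataFrame        # rows: class; columns: N grid (all frames)
    acc_table_nonempty: pd.DataFrame   # same, frames with nonempty truth only
    both_empty_counts: dict[str, int]


def evaluate_dataset(pred_maps: list[np.ndarray], truths: list[MaskSet],
                     n_grid=DEFAULT_N_GRID, threshold: float = 0.5) -> IoUSummary:
    """Score per-class certainty maps against ground-truth masks.

    ``pred_maps`` holds one (H, W, 3) certainty array per frame in class
    order (cornea, tips, incision). IoU is computed after binarization at
    ``threshold``; the detection-rate table is reported both over all
    frames (both-empty frames scoring IoU 1.0, counted separately) and
    over frames whose ground truth is nonempty.
    """
    if len(pred_maps) != len(truths):
        raise ValueError("predictions and ground truths must align")
    rows = []
    both_empty = {cls: 0 for cls in MaskSet.CLASSES}
    for t, (pm, truth) in enumerate(zip(pred_maps, truths)):
        for ci, cls in enumerate(MaskSet.CLASSES):
            pred = binarize(pm[..., ci], threshold)
            gt = getattr(truth, cls)
            empty = (gt.sum() == 0)
            if empty and pred.sum() == 0:
                both_empty[cls] += 1
            rows.append({"frame": t, "class": cls, "iou": iou(pred, gt),
                         "truth_empty": bool(empty)})
    per_frame = pd.DataFrame(rows)
    def table(df: pd.DataFrame) -> pd.DataFrame:
        data = {}
        for cls in MaskSet.CLASSES:
            vals = df.loc[df["class"] == cls, "iou"].to_numpy()
            data[cls] = [100.0 * acc_iou_ge(vals, n) if vals.size else np.nan
                         for n in n_grid]
        return pd.DataFrame(data, index=list(n_grid)).T
    return IoUSummary(per_frame, table(per_frame),
                      table(per_frame[~per_frame["truth_empty"]]),
                      both_empty)
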