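"""Evaluation metrics: PSNR, SSIM, pixelwise segmentation scores, and
skeleton topological accuracy against ground-truth landmarks."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .graph import build_kernel_bank, detect_nodes, merge_points

__all__ = [
    "psnr",
    "ssim",
    "SegmentationScore",
    "segmentation_metrics",
    "TopologyScore",
    "topological_accuracy",
    "connectivity_check",
]


def _check_pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def psnr(ref: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(peak^2 / MSE); identical
    images give +inf."""
    ref, test = _check_pair(ref, test)
    mse = float(((ref - test) ** 2).mean())
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def ssim(ref: np.ndarray, test: np.ndarray) -> float:
    """Mean structural similarity (7-px window, K1=0.01, K2=0.03, unit
    data range)."""
    ref, test = _check_pair(ref, test)
    return float(
        structural_similarity(ref, test, win_size=7, K1=0.01, K2=0.03, data_range=1.0)
    )


@dataclass(frozen=True)
class SegmentationScore:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float


def segmentation_metrics(pred: np.ndarray, gt: np.ndarray) -> SegmentationScore:
    """Pixelwise confusion counts and derived metrics; zero-division cases
    give 0 with a warning."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    tn = int((~pred & ~gt).sum())

    def safe(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0", stacklevel=3)
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f1 = safe(2 * tp, 2 * tp + fp + fn, "f1")
    accuracy = (tp + tn) / pred.size
    return SegmentationScore(tp, fp, fn, tn, accuracy, precision, recall, f1)


@dataclass(frozen=True)
class TopologyScore:
    matched_points: int
    total_gt_points: int
    tolerance_px: float

    @property
    def accuracy(self) -> float:
        return self.matched_points / self.total_gt_points


def _greedy_match(
    pred: Sequence[tuple[float, float]], gt: Sequence[tuple[float, float]], tol: float
) -> int:
    """One-to-one greedy matching, smallest distance first."""
    if not pred or not gt:
        return 0
    p = np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    d = np.hypot(p[:, None, 0] - g[None, :, 0], p[:, None, 1] - g[None, :, 1])
    pairs = [(d[i, j], i, j) for i in range(len(p)) for j in range(len(g)) if d[i, j] <= tol]
    pairs.sort()
    used_p: set[int] = set()
    used_g: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_p or j in used_g:
            continue
        used_p.add(i)
        used_g.add(j)
        matched += 1
    return matched


def topological_accuracy(
    pred_skel: np.ndarray,
    gt_junctions: Sequence[tuple[float, float]],
    gt_endpoints: Sequence[tuple[float, float]],
    tol: float = 3.0,
) -> TopologyScore:
    """Fraction of ground-truth landmarks recovered on a skeleton.

    Junctions and endpoints are detected on the skeleton (hit-or-miss bank
    plus single-neighbor rule, junction pixels merged at 4 px) and matched
    one-to-one to the ground-truth points of the same kind, greedily by
    distance within ``tol`` pixels."""
    total = len(gt_junctions) + len(gt_endpoints)
    if total == 0:
        raise ValueError("topological accuracy undefined without ground-truth points")
    raw_j, eps = detect_nodes(np.asarray(pred_skel, dtype=bool), build_kernel_bank())
    pred_j = merge_points(raw_j, radius=4.0) if raw_j else []
    pred_e = [(float(r), float(c)) for r, c in eps]
    matched = _greedy_match(pred_j, list(gt_junctions), tol) + _greedy_match(
        pred_e, list(gt_endpoints), tol
    )
    return TopologyScore(matched_points=matched, total_gt_points=total, tolerance_px=tol)


def connectivity_check(pred_skel: np.ndarray, gt_mask: np.ndarray) -> bool:
    """True when the skeleton preserves the ground-truth mask's number of
    8-connected components (reported alongside, not folded into, the
    topological accuracy)."""
    s8 = np.ones((3, 3), dtype=bool)
    _, n_pred = ndimage.label(np.asarray(pred_skel, bool), structure=s8)
    _, n_gt = ndimage.label(np.asarray(gt_mask, bool), structure=s8)
    return n_pred == n_gt
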