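"""Segmentation evaluation: overlap, surface distances, ROC."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.metrics import roc_curve as sk_roc_curve


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); 1 when both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / float(denom)


def _surface_points(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """mm coordinates of surface voxels (face-neighbor boundary)."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    surf = mask & ~eroded
    return np.array(np.nonzero(surf)).T * np.asarray(spacing, dtype=float)


def _directed_distances(a: np.ndarray, b: np.ndarray, spacing) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if not a.any() or not b.any():
        raise ValueError("surface distances need two non-empty masks")
    pa = _surface_points(a, spacing)
    pb = _surface_points(b, spacing)
    d_ab, _ = cKDTree(pb).query(pa, workers=-1)
    d_ba, _ = cKDTree(pa).query(pb, workers=-1)
    return d_ab, d_ba


def hausdorff(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between surface voxel sets, in mm."""
    d_ab, d_ba = _directed_distances(a, b, spacing)
    return float(max(d_ab.max(), d_ba.max()))


def mean_surface_distance(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric mean of surface-to-nearest-surface distances, in mm."""
    d_ab, d_ba = _directed_distances(a, b, spacing)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))


def roc_auc(
    prob: np.ndarray, gt: np.ndarray, eval_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve and trapezoid AUC of a probability map against a mask.

    Returns ``(fpr, tpr, auc)``; requires both classes inside the mask.
    """
    prob = np.asarray(prob)
    gt = np.asarray(gt, dtype=bool)
    if eval_mask is not None:
        prob = prob[np.asarray(eval_mask, dtype=bool)]
        gt = gt[np.asarray(eval_mask, dtype=bool)]
    else:
        prob = prob.ravel()
        gt = gt.ravel()
    if gt.all() or not gt.any():
        raise ValueError("ground truth has a single class inside the evaluation mask")
    fpr, tpr, _ = sk_roc_curve(gt.astype(int), prob)
    return fpr, tpr, float(np.trapezoid(tpr, fpr))


def roc_to_csv(fpr: np.ndarray, tpr: np.ndarray, path) -> None:
    """Write an ROC curve as a two-column CSV (fpr, tpr)."""
    import pandas as pd

    pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(path, index=False, float_format="%.6f")
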