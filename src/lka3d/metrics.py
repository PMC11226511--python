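"""Evaluation metrics: Dice overlap, 95th-percentile Hausdorff distance,
tumor-region maps, paired t-tests, and tabulated evaluation reports.

HD95 is computed as the 95th percentile of the pooled symmetric surface
distances between the two mask boundaries (distance-transform based),
in millimetres via the voxel spacing.  The challenge convention for
false-positive enhancing-tumor predictions (empty reference, non-empty
prediction) assigns Dice 0 and HD95 373.13.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "BRATS_HD95_PENALTY",
    "dice_score",
    "hd95",
    "surface_distances",
    "paired_ttest",
    "brats_region_maps",
    "EvalReport",
    "evaluate_cases",
]

BRATS_HD95_PENALTY = 373.13


def _as_mask(x) -> np.ndarray:
    m = np.asarray(x)
    return m.astype(bool)


def dice_score(pred, gt, fp_penalty: float | None = None) -> float:
    """Dice = 2|X∩Y| / (|X|+|Y|); both-empty masks score 1 by convention."""
    pred, gt = _as_mask(pred), _as_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    np_, ng = int(pred.sum()), int(gt.sum())
    if np_ == 0 and ng == 0:
        return 1.0
    if ng == 0 and np_ > 0 and fp_penalty is not None:
        return 0.0
    inter = int(np.logical_and(pred, gt).sum())
    return 2.0 * inter / (np_ + ng)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """6-connected boundary: mask voxels lost under one erosion step."""
    structure = ndimage.generate_binary_structure(3, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=structure, border_value=0)


def surface_distances(pred, gt, spacing=(1.0, 1.0, 1.0)) -> tuple[np.ndarray, np.ndarray]:
    """Directed boundary distances (pred->gt, gt->pred) in mm."""
    pred, gt = _as_mask(pred), _as_mask(gt)
    bp, bg = _boundary(pred), _boundary(gt)
    dt_gt = ndimage.distance_transform_edt(~bg, sampling=spacing)
    dt_pred = ndimage.distance_transform_edt(~bp, sampling=spacing)
    return dt_gt[bp], dt_pred[bg]


def hd95(pred, gt, spacing=(1.0, 1.0, 1.0), fp_penalty: float | None = None,
         method: str = "pooled") -> float:
    """95th-percentile Hausdorff distance in millimetres.

    ``method="pooled"`` (default) takes the 95th percentile of the pooled
    directed surface distances of both directions; ``"directed_max"``
    instead takes the max of the two directed 95th percentiles.
    """
    pred, gt = _as_mask(pred), _as_mask(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive: {spacing}")
    np_, ng = int(pred.sum()), int(gt.sum())
    if np_ == 0 and ng == 0:
        return 0.0
    if ng == 0 and np_ > 0 and fp_penalty is not None:
        return float(fp_penalty)
    if np_ == 0 or ng == 0:
        return float("inf")
    d_pg, d_gp = surface_distances(pred, gt, spacing)
    if method == "pooled":
        return float(np.percentile(np.concatenate([d_pg, d_gp]), 95))
    if method == "directed_max":
        return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))
    raise ValueError(f"unknown method {method!r}")


def paired_ttest(scores_a, scores_b) -> float:
    """Two-sided paired t-test p-value on per-case score differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D score vectors")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least two cases")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    t = d.mean() / (sd / np.sqrt(n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def brats_region_maps(label) -> dict[str, np.ndarray]:
    """Nested tumor-region masks from a label volume.

    Labels: 0 background, 1 necrotic/non-enhancing core, 2 edema,
    4 enhancing tumor.  Regions: ET = {4}; TC = ET + {1}; WT = TC + {2};
    so ET ⊆ TC ⊆ WT.
    """
    lab = np.asarray(label)
    known = {0, 1, 2, 4}
    present = set(np.unique(lab).tolist())
    if not present <= known:
        raise ValueError(f"unknown label values {sorted(present - known)}")
    et = lab == 4
    tc = et | (lab == 1)
    wt = tc | (lab == 2)
    return {"ET": et, "TC": tc, "WT": wt}


@dataclass
class EvalReport:
    """Per-case, per-class Dice and HD95 plus aggregates."""

    dice: pd.DataFrame  # index: case id, columns: class names
    hd95: pd.DataFrame

    def aggregate(self) -> pd.DataFrame:
        """"mean (std)" per class plus the cross-class mean column."""
        rows = {}
        for metric, df in (("Dice", self.dice), ("HD95", self.hd95)):
            with_mean = df.assign(mean=df.mean(axis=1))
            rows[metric] = {
                c: f"{with_mean[c].mean():.2f} ({with_mean[c].std(ddof=1):.2f})"
                for c in with_mean.columns
            }
        return pd.DataFrame(rows).T

    def case_means(self) -> pd.Series:
        return self.dice.mean(axis=1)

    def compare(self, other: "EvalReport") -> pd.DataFrame:
        """Pairwise paired-t-test p-values per class and on the mean."""
        out = {}
        for metric, a, b in (("Dice", self.dice, other.dice),
                             ("HD95", self.hd95, other.hd95)):
            am = a.assign(mean=a.mean(axis=1))
            bm = b.assign(mean=b.mean(axis=1))
            out[metric] = {
                c: paired_ttest(am[c].to_numpy(), bm[c].to_numpy())
                for c in am.columns
            }
        return pd.DataFrame(out).T


def evaluate_cases(pred_labels: dict, gt_labels: dict, class_ids: dict[str, int],
                   spacing=(1.0, 1.0, 1.0),
                   fp_penalty_classes: dict[str, float] | None = None) -> EvalReport:
    """Per-case, per-class evaluation of integer label volumes.

    ``class_ids`` maps class name -> label value; ``fp_penalty_classes``
    maps class name -> HD95 penalty for empty-reference false positives
    (the corresponding Dice penalty is 0).
    """
    fp_penalty_classes = fp_penalty_classes or {}
    dice_rows, hd_rows = {}, {}
    for case, gt in gt_labels.items():
        if case not in pred_labels:
            raise KeyError(f"missing prediction for case {case!r}")
        pred = pred_labels[case]
        drow, hrow = {}, {}
        for name, cid in class_ids.items():
            pm, gm = pred == cid, gt == cid
            pen = fp_penalty_classes.get(name)
            drow[name] = dice_score(pm, gm, fp_penalty=pen)
            hrow[name] = hd95(pm, gm, spacing=spacing, fp_penalty=pen)
        dice_rows[case] = drow
        hd_rows[case] = hrow
    return EvalReport(
        dice=pd.DataFrame.from_dict(dice_rows, orient="index"),
        hd95=pd.DataFrame.from_dict(hd_rows, orient="index"),
    )
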