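"""BraTS-style evaluation: region composition, Dice, 95th-percentile Hausdorff.

The three nested evaluation regions are derived from the raw labels:
whole tumor WT = {1, 2, 4}, tumor core TC = {1, 4}, enhancing tumor ET = {4}.

Dice is the count form 2·TP / (FP + 2·TP + FN).  HD95 is the 95th percentile
of the pooled symmetric set of surface-to-surface distances, computed with an
exact Euclidean distance transform; surfaces are mask voxels with at least one
6-connected background neighbor (array borders count as background).

Empty-mask conventions are explicit because low-grade-glioma cases may lack
enhancing tumor entirely: both masks empty → Dice 1, HD95 0; exactly one
empty → Dice 0 and HD95 NaN (excluded from means and counted), or a fixed
penalty if the leaderboard-style variant is requested.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import LabelVolume

REGIONS = ("wt", "tc", "et")
REGION_LABELS = {"wt": (1, 2, 4), "tc": (1, 4), "et": (4,)}


@dataclasses.dataclass
class RegionMasks:
    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)


@dataclasses.dataclass
class CaseMetrics:
    case_id: str
    dice_wt: float
    dice_tc: float
    dice_et: float
    hd95_wt: float
    hd95_tc: float
    hd95_et: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compose_regions(label: LabelVolume | np.ndarray) -> RegionMasks:
    """Derive the nested WT/TC/ET masks from a raw label volume."""
    arr = label.data if isinstance(label, LabelVolume) else np.asarray(label)
    bad = set(np.unique(arr).tolist()) - {0, 1, 2, 4}
    if bad:
        raise ValueError(f"invalid label values {sorted(bad)}")
    masks = {r: np.isin(arr, REGION_LABELS[r]) for r in REGIONS}
    return RegionMasks(**masks)


def dice_score(pred: np.ndarray, gt: np.ndarray) -> float:
    """Overlap 2·TP / (FP + 2·TP + FN); 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.logical_and(pred, gt).sum())
    fp = int(pred.sum()) - tp
    fn = int(gt.sum()) - tp
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0
    denom = fp + 2 * tp + fn
    return 2.0 * tp / denom


def _surface(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a 6-connected background neighbor (borders included)."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hausdorff95(pred: np.ndarray, gt: np.ndarray,
                spacing: tuple = (1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled symmetric surface distances, in mm.

    Returns 0.0 when both masks are empty and NaN when exactly one is (no
    surface distance is defined).  Symmetric by construction: distances from
    both surfaces are pooled before the percentile is taken.
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p_any, g_any = bool(pred.any()), bool(gt.any())
    if not p_any and not g_any:
        return 0.0
    if p_any != g_any:
        return float("nan")
    ps = _surface(pred)
    gs = _surface(gt)
    # exact EDT to the nearest surface voxel of the other mask
    dt_gt = ndimage.distance_transform_edt(~gs, sampling=spacing)
    dt_pred = ndimage.distance_transform_edt(~ps, sampling=spacing)
    pooled = np.concatenate([dt_gt[ps], dt_pred[gs]])
    return float(np.percentile(pooled, 95))


def evaluate_case(pred_label: LabelVolume | np.ndarray,
                  gt_label: LabelVolume | np.ndarray,
                  case_id: str = "",
                  spacing: tuple = (1.0, 1.0, 1.0),
                  empty_penalty: float | None = None) -> CaseMetrics:
    """Dice and HD95 for each of WT/TC/ET.

    ``empty_penalty`` switches the one-mask-empty HD95 convention from NaN to
    a fixed value (the leaderboard-style penalty, conventionally 373.13 mm).
    """
    pred_arr = pred_label.data if isinstance(pred_label, LabelVolume) else np.asarray(pred_label)
    gt_arr = gt_label.data if isinstance(gt_label, LabelVolume) else np.asarray(gt_label)
    if pred_arr.shape != gt_arr.shape:
        raise ValueError(f"shape mismatch: {pred_arr.shape} vs {gt_arr.shape}")
    pred_masks = compose_regions(pred_arr)
    gt_masks = compose_regions(gt_arr)
    values = {}
    for r in REGIONS:
        values[f"dice_{r}"] = dice_score(pred_masks[r], gt_masks[r])
        hd = hausdorff95(pred_masks[r], gt_masks[r], spacing=spacing)
        if np.isnan(hd) and empty_penalty is not None:
            hd = empty_penalty
        values[f"hd95_{r}"] = hd
    return CaseMetrics(case_id=case_id, **values)


def aggregate(metrics: list[CaseMetrics]) -> pd.DataFrame:
    """Per-metric mean over defined values plus a count of undefined cases.

    Returns a two-row frame indexed ('mean', 'n_undefined') with one column
    per metric; NaN sentinels are excluded from means and tallied instead.
    """
    if not metrics:
        raise ValueError("aggregate requires at least one case")
    frame = pd.DataFrame([m.as_dict() for m in metrics]).drop(columns="case_id")
    means = frame.mean(skipna=True)
    undefined = frame.isna().sum()
    return pd.DataFrame({"mean": means, "n_undefined": undefined}).T


def metrics_table(metrics: list[CaseMetrics]) -> pd.DataFrame:
    """Per-case table with the CSV column layout (case_id, dice_*, hd95_*)."""
    return pd.DataFrame([m.as_dict() for m in metrics])
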