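"""Segmentation evaluation: overlap metrics, HD95 and the BraTS label ->
WT/TC/ET region decomposition.

Regions: whole tumor = labels {1,2,4}, tumor core = {1,4}, enhancing
tumor = {4}.  Empty-mask convention for the overlap metrics: both masks
empty scores 1 (a perfect prediction on a tumor-free case is perfect).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    DegenerateInputError,
    InvalidInputError,
    LabelVolume,
    VALID_LABELS,
)

REGIONS = ("wt", "tc", "et")
_REGION_LABELS = {"wt": (1, 2, 4), "tc": (1, 4), "et": (4,)}


@dataclass
class RegionMasks:
    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __getitem__(self, region: str) -> np.ndarray:
        return getattr(self, region)


@dataclass
class RegionMetrics:
    dsc: float
    recall: float
    precision: float
    iou: float
    hd95: float
    n_truth: int
    n_pred: int


@dataclass
class MetricsReport:
    per_region: dict[str, RegionMetrics] = field(default_factory=dict)

    def as_rows(self, case_id: str = "") -> list[dict]:
        rows = []
        for region, m in self.per_region.items():
            rows.append(
                {
                    "case": case_id,
                    "region": region,
                    "dsc": m.dsc,
                    "recall": m.recall,
                    "precision": m.precision,
                    "iou": m.iou,
                    "hd95": m.hd95,
                    "n_truth": m.n_truth,
                    "n_pred": m.n_pred,
                }
            )
        return rows


def region_masks(labels: LabelVolume | np.ndarray) -> RegionMasks:
    lab = labels.data if isinstance(labels, LabelVolume) else np.asarray(labels)
    bad = set(np.unique(lab)) - set(VALID_LABELS)
    if bad:
        raise InvalidInputError(f"unknown label values {sorted(bad)}; allowed {{0,1,2,4}}")
    return RegionMasks(
        wt=np.isin(lab, _REGION_LABELS["wt"]),
        tc=np.isin(lab, _REGION_LABELS["tc"]),
        et=np.isin(lab, _REGION_LABELS["et"]),
    )


def _as_masks(g, o) -> tuple[np.ndarray, np.ndarray]:
    gm = np.asarray(g, dtype=bool)
    om = np.asarray(o, dtype=bool)
    if gm.shape != om.shape:
        raise InvalidInputError(f"shape mismatch {gm.shape} vs {om.shape}")
    return gm, om


def dsc(g, o) -> float:
    """Dice similarity 2|G∩O| / (|G|+|O|); 1 if both masks are empty."""
    gm, om = _as_masks(g, o)
    denom = int(gm.sum()) + int(om.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((gm & om).sum()) / denom


def recall(g, o) -> float:
    """|G∩O| / |G|; if G is empty: 1 when O is also empty, else 0."""
    gm, om = _as_masks(g, o)
    n_g = int(gm.sum())
    if n_g == 0:
        return 1.0 if int(om.sum()) == 0 else 0.0
    return int((gm & om).sum()) / n_g


def precision(g, o) -> float:
    """|G∩O| / |O|; if O is empty: 1 when G is also empty, else 0."""
    gm, om = _as_masks(g, o)
    n_o = int(om.sum())
    if n_o == 0:
        return 1.0 if int(gm.sum()) == 0 else 0.0
    return int((gm & om).sum()) / n_o


def iou(g, o) -> float:
    """Jaccard |G∩O| / |G∪O|; 1 if both masks are empty."""
    gm, om = _as_masks(g, o)
    union = int((gm | om).sum())
    if union == 0:
        return 1.0
    return int((gm & om).sum()) / union


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """6-connectivity boundary: mask voxels with at least one face neighbour
    outside the mask (the array border counts as outside)."""
    m = np.asarray(mask, dtype=bool)
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(m, structure=struct, border_value=0)
    return m & ~eroded


def hd95(
    g,
    o,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    empty_sentinel: float | None = None,
) -> float:
    """95th percentile (linear interpolation) of the pooled symmetric
    boundary-distance distribution, in physical units.

    Raises on an empty mask unless ``empty_sentinel`` is given.
    """
    gm, om = _as_masks(g, o)
    if any(s <= 0 for s in spacing):
        raise InvalidInputError("spacing must be positive")
    if not gm.any() or not om.any():
        if empty_sentinel is not None:
            return float(empty_sentinel)
        raise DegenerateInputError("hd95 undefined for empty masks")
    bg = boundary_voxels(gm)
    bo = boundary_voxels(om)
    # distance from every voxel to the nearest boundary voxel of the other mask
    dist_to_bo = ndimage.distance_transform_edt(~bo, sampling=spacing)
    dist_to_bg = ndimage.distance_transform_edt(~bg, sampling=spacing)
    pooled = np.concatenate([dist_to_bo[bg], dist_to_bg[bo]])
    return float(np.percentile(pooled, 95))


def evaluate_case(
    truth: LabelVolume | np.ndarray,
    pred: LabelVolume | np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    hd95_empty_sentinel: float = float("nan"),
) -> MetricsReport:
    """All metrics for the three BraTS regions of one case."""
    gm = region_masks(truth)
    om = region_masks(pred)
    report = MetricsReport()
    for region in REGIONS:
        g_mask, o_mask = gm[region], om[region]
        both_empty = not g_mask.any() and not o_mask.any()
        report.per_region[region] = RegionMetrics(
            dsc=dsc(g_mask, o_mask),
            recall=recall(g_mask, o_mask),
            precision=precision(g_mask, o_mask),
            iou=iou(g_mask, o_mask),
            hd95=0.0 if both_empty else hd95(g_mask, o_mask, spacing, empty_sentinel=hd95_empty_sentinel),
            n_truth=int(g_mask.sum()),
            n_pred=int(o_mask.sum()),
        )
    return report
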