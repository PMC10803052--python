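"""Compound segmentation loss (BCE + Dice) and IoU/F1 evaluation metrics.

Loss functions accept either plain arrays (returning a float) or autodiff
tensors for the prediction (returning a scalar :class:`~cgmunet.nn.Tensor`
through which gradients flow).  The ground truth is always a strictly binary
array.

Conventions (all logged in the JSON summary):

* BCE uses the standard two-term form with probabilities clipped to
  ``[eps, 1 - eps]``, ``eps = 1e-7``, and a mean reduction over pixels.
* Dice is computed on soft probabilities during training with an additive
  smoothing constant (default 1.0) in numerator and denominator.
* The combined training loss is ``0.5 * BCE + Dice``.
* Metrics binarize at threshold 0.5; if both masks are empty the score is 1;
  reported aggregates are arithmetic means of per-image scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import ValidationError
from .nn import Tensor

__all__ = ["bce_loss", "dice_loss", "combined_loss", "iou_score", "f1_score",
           "MetricsReport", "EPS", "DICE_SMOOTH", "DEFAULT_THRESHOLD"]

EPS = 1e-7
DICE_SMOOTH = 1.0
DEFAULT_THRESHOLD = 0.5


def _check_binary(mask, name: str = "truth") -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must contain only 0 and 1")
    return arr.astype(np.float64)


def bce_loss(truth, pred_prob, eps: float = EPS):
    """Two-term binary cross-entropy, mean over all pixels."""
    t = _check_binary(truth)
    if isinstance(pred_prob, Tensor):
        tt = Tensor(t.astype(pred_prob.dtype))
        p = pred_prob.clip(eps, 1.0 - eps)
        return -(tt * p.log() + (1.0 - tt) * (1.0 - p).log()).mean()
    p = np.clip(np.asarray(pred_prob, dtype=np.float64), eps, 1.0 - eps)
    return float(-(t * np.log(p) + (1.0 - t) * np.log1p(-p)).mean())


def dice_loss(truth, pred_prob, smooth: float = DICE_SMOOTH):
    """Soft Dice loss: ``1 - (2|Y∩Ŷ| + s) / (|Y| + |Ŷ| + s)``.

    Intersection and cardinalities use the soft probabilities, so the loss is
    differentiable; it is 0 iff the prediction matches the truth exactly (up
    to smoothing) and at most 1.
    """
    t = _check_binary(truth)
    if isinstance(pred_prob, Tensor):
        tt = Tensor(t.astype(pred_prob.dtype))
        inter = (tt * pred_prob).sum()
        card = tt.sum() + pred_prob.sum()
        return 1.0 - (2.0 * inter + smooth) / (card + smooth)
    p = np.asarray(pred_prob, dtype=np.float64)
    inter = float((t * p).sum())
    card = float(t.sum() + p.sum())
    return float(1.0 - (2.0 * inter + smooth) / (card + smooth))


def combined_loss(truth, pred_prob, smooth: float = DICE_SMOOTH,
                  eps: float = EPS):
    """Training loss: ``0.5 * BCE + Dice``."""
    return 0.5 * bce_loss(truth, pred_prob, eps) \
        + dice_loss(truth, pred_prob, smooth)


def iou_score(truth, pred_mask) -> float:
    """Intersection over union of two binary masks (both empty -> 1)."""
    t = _check_binary(truth, "truth")
    p = _check_binary(pred_mask, "pred_mask")
    if t.shape != p.shape:
        raise ValidationError(f"mask shapes differ: {t.shape} vs {p.shape}")
    inter = float((t * p).sum())
    union = float(t.sum() + p.sum() - inter)
    if union == 0.0:
        return 1.0
    return inter / union


def f1_score(truth, pred_mask) -> float:
    """Set-based F1 (Dice coefficient): ``2|∩| / (|Y| + |Ŷ|)``; both empty -> 1."""
    t = _check_binary(truth, "truth")
    p = _check_binary(pred_mask, "pred_mask")
    if t.shape != p.shape:
        raise ValidationError(f"mask shapes differ: {t.shape} vs {p.shape}")
    inter = float((t * p).sum())
    card = float(t.sum() + p.sum())
    if card == 0.0:
        return 1.0
    return 2.0 * inter / card


@dataclass
class MetricsReport:
    """Per-image and aggregate IoU/F1 scores at a fixed threshold."""

    per_image: list = field(default_factory=list)  # (id, iou, f1) triples
    threshold: float = DEFAULT_THRESHOLD

    @property
    def mean_iou(self) -> float:
        return float(np.mean([r[1] for r in self.per_image])) \
            if self.per_image else float("nan")

    @property
    def mean_f1(self) -> float:
        return float(np.mean([r[2] for r in self.per_image])) \
            if self.per_image else float("nan")

    def add(self, image_id: str, truth, pred_prob) -> tuple[float, float]:
        mask = (np.asarray(pred_prob) > self.threshold).astype(np.uint8)
        iou = iou_score(truth, mask)
        f1 = f1_score(truth, mask)
        self.per_image.append((image_id, iou, f1))
        return iou, f1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_image, columns=["id", "iou", "f1"])

    def write(self, csv_path, json_path=None) -> None:
        """Write the per-image CSV and a JSON summary of the conventions."""
        csv_path = Path(csv_path)
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            summary = {
                "n_images": len(self.per_image),
                "mean_iou": self.mean_iou,
                "mean_f1": self.mean_f1,
                "threshold": self.threshold,
                "conventions": {
                    "aggregation": "mean of per-image scores",
                    "both_masks_empty": 1.0,
                    "bce": "two-term, eps 1e-7",
                    "dice_smooth": DICE_SMOOTH,
                },
            }
            Path(json_path).write_text(json.dumps(summary, indent=2))
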