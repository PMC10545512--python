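"""Marginalized (partial-label) segmentation loss.

Clinical annotation protocols are inconsistent: the myocardium is often
segmented at ED but not at ES, so a training frame may simply lack some
classes.  Masking those voxels out discards signal; instead this loss
*marginalizes*: for every class absent from a frame's annotation protocol,
its predicted probability is folded into background,

    q_bg = p_bg + sum over absent c of p_c,

and the standard composite cross-entropy + soft-Dice loss is evaluated on
the folded distribution over the present classes only.  Folding preserves
normalization, so the loss is exactly invariant to how the network splits
mass between an absent class and background, and reduces exactly to the
standard loss when every class is present.

Pure NumPy; usable as a reference by any training backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import BG

__all__ = ["AnnotatedFrame", "marginalized_loss", "N_CLASSES", "DICE_SMOOTH"]

#: canonical class count: background, LVBP, MYO, RVBP
N_CLASSES = 4

#: additive smoothing in numerator and denominator of the soft Dice
DICE_SMOOTH = 1e-5

_PROB_ATOL = 1e-6
_LOG_FLOOR = 1e-12  # keeps the loss finite for zero predicted probability


@dataclass
class AnnotatedFrame:
    """Predicted probabilities + reference labels for one (partially) annotated frame.

    ``probs`` has shape ``(..., n_classes)`` (class axis last) with each
    voxel's row summing to 1; ``labels`` has the leading shape and holds
    class ids drawn from ``present_classes``, which always contains
    background.
    """

    probs: np.ndarray
    labels: np.ndarray
    present_classes: tuple[int, ...] = field(default=tuple(range(N_CLASSES)))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels)
        self.present_classes = tuple(sorted(set(int(c) for c in self.present_classes)))
        if self.probs.shape[:-1] != self.labels.shape:
            raise ValueError(
                f"probs leading shape {self.probs.shape[:-1]} != labels shape "
                f"{self.labels.shape}"
            )
        if BG not in self.present_classes:
            raise ValueError("background must always be a present class")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = self.probs.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_PROB_ATOL):
            worst = float(np.abs(sums - 1.0).max())
            raise ValueError(f"probability rows must sum to 1 (worst deviation {worst:.2e})")
        bad = set(np.unique(self.labels).tolist()) - set(self.present_classes)
        if bad:
            raise ValueError(
                f"reference labels {sorted(bad)} belong to absent classes "
                f"(present: {self.present_classes})"
            )

    @property
    def n_classes(self) -> int:
        return self.probs.shape[-1]


def _fold(frame: AnnotatedFrame) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Fold absent-class probability into background.

    Returns (folded probs over present classes, relabelled references,
    present class ids in folded-channel order).
    """
    present = list(frame.present_classes)
    absent = [c for c in range(frame.n_classes) if c not in present]
    q = frame.probs[..., present].copy()
    bg_channel = present.index(BG)
    if absent:
        q[..., bg_channel] += frame.probs[..., absent].sum(axis=-1)
    remap = {c: i for i, c in enumerate(present)}
    labels = np.vectorize(remap.__getitem__, otypes=[np.int64])(frame.labels)
    return q, labels, present


def marginalized_loss(
    frame: AnnotatedFrame, ce_weight: float = 1.0, dice_weight: float = 1.0
) -> float:
    """Composite CE + (1 - mean soft Dice) on the marginalized distribution.

    ``loss = ce_weight * CE' + dice_weight * (1 - meanDice')`` where CE' is
    the per-voxel mean cross-entropy of the folded probabilities against the
    reference and Dice' averages the smoothed soft Dice over the *present*
    non-background classes.  Always finite and non-negative; identically the
    standard composite loss when all classes are present.
    """
    q, labels, present = _fold(frame)
    flat_q = q.reshape(-1, q.shape[-1])
    flat_labels = labels.reshape(-1)
    picked = flat_q[np.arange(flat_labels.size), flat_labels]
    ce = float(-np.mean(np.log(np.maximum(picked, _LOG_FLOOR))))

    dice_scores = []
    for channel, cls in enumerate(present):
        if cls == BG:
            continue
        p = flat_q[:, channel]
        g = (flat_labels == channel).astype(float)
        dice_scores.append(
            (2.0 * float(np.sum(p * g)) + DICE_SMOOTH)
            / (float(np.sum(p)) + float(np.sum(g)) + DICE_SMOOTH)
        )
    dice_term = 1.0 - float(np.mean(dice_scores)) if dice_scores else 0.0
    return ce_weight * ce + dice_weight * dice_term
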