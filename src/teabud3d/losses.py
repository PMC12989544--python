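"""Neural-field training losses as standalone functions over ray batches.

These are the supervision terms used when fitting a semantic, depth-supervised
radiance field: a photometric term (squared L2 on ray colors), a semantic
binary cross-entropy on per-ray bud probability, and an L1 depth term, with
the total being a weighted sum. No gradients, sampling or rendering here —
pure numerics for evaluation and testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidBatchError, InvalidWeightsError

__all__ = ["RayBatch", "LossWeights", "image_loss", "semantic_loss",
           "depth_loss", "total_loss", "BCE_EPS"]

BCE_EPS = 1e-7  # probability clip before taking logs


@dataclass
class RayBatch:
    """A batch of rays with true/predicted color, bud probability and depth."""

    true_color: np.ndarray   # (n, 3) in [0, 1]
    pred_color: np.ndarray   # (n, 3) in [0, 1]
    true_bud_prob: np.ndarray
    pred_bud_prob: np.ndarray
    true_depth: np.ndarray
    pred_depth: np.ndarray

    def __post_init__(self) -> None:
        self.true_color = np.atleast_2d(np.asarray(self.true_color, dtype=float))
        self.pred_color = np.atleast_2d(np.asarray(self.pred_color, dtype=float))
        for name in ("true_bud_prob", "pred_bud_prob", "true_depth", "pred_depth"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        n = len(self.true_color)
        if n == 0:
            raise InvalidBatchError("empty ray batch")
        for name in ("pred_color", "true_bud_prob", "pred_bud_prob",
                     "true_depth", "pred_depth"):
            if len(getattr(self, name)) != n:
                raise InvalidBatchError(
                    f"{name} has length {len(getattr(self, name))}, expected {n}")
        for name in ("true_bud_prob", "pred_bud_prob"):
            p = getattr(self, name)
            if np.any(p < 0) or np.any(p > 1):
                raise InvalidBatchError(f"{name} must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.true_color)


@dataclass(frozen=True)
class LossWeights:
    """Weights of the semantic and depth terms in the total objective."""

    lambda_sem: float = 1.0
    lambda_depth: float = 0.1

    def __post_init__(self) -> None:
        if self.lambda_sem < 0 or self.lambda_depth < 0:
            raise InvalidWeightsError("loss weights must be non-negative")


def image_loss(batch: RayBatch) -> float:
    """Photometric loss: mean over rays of the squared L2 color error."""
    err = batch.true_color - batch.pred_color
    return float(np.mean(np.sum(err ** 2, axis=1)))


def semantic_loss(batch: RayBatch) -> float:
    """Binary cross-entropy between true and predicted bud probabilities.

    Predicted probabilities are clipped to [1e-7, 1 - 1e-7] before the logs.
    """
    p = batch.true_bud_prob
    q = np.clip(batch.pred_bud_prob, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(p * np.log(q) + (1.0 - p) * np.log(1.0 - q)))


def depth_loss(batch: RayBatch) -> float:
    """Depth supervision: mean absolute error between true and predicted depth."""
    return float(np.mean(np.abs(batch.true_depth - batch.pred_depth)))


def total_loss(batch: RayBatch, w: LossWeights = LossWeights()) -> float:
    """image + lambda_sem * semantic + lambda_depth * depth."""
    return (image_loss(batch)
            + w.lambda_sem * semantic_loss(batch)
            + w.lambda_depth * depth_loss(batch))
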