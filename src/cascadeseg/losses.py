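"""Cross-entropy and soft Dice losses, and the two-stage composite objective.

The composite objective weighs the stages as

    L = 0.5 · L_CE(stage 1) + 0.5 · L_CE(stage 2) + L_DC(stage 2)

so the coarse stage is supervised by cross-entropy alone while the refining
stage also optimizes overlap directly.  Cross-entropy is averaged over voxels
(scale-independent of crop size); the Dice loss is soft (softmax
probabilities), computed per foreground class only — background dominance is
exactly the imbalance the Dice term exists to counter — and averaged over the
three foreground classes.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor, exp, log_softmax, tsum

DICE_EPS = 1e-5
FOREGROUND_CLASSES = (1, 2, 3)


@dataclasses.dataclass
class LossWeights:
    w_ce1: float = 0.5
    w_ce2: float = 0.5
    w_dc2: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w_ce1, self.w_ce2, self.w_dc2) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclasses.dataclass
class LossReport:
    ce1: float
    ce2: float
    dc2: float
    total: float


def _check_shapes(logits: Tensor, target: np.ndarray) -> None:
    if logits.data.shape != target.shape:
        raise ValueError(f"logits shape {logits.data.shape} != target {target.shape}")


def cross_entropy(logits: Tensor | np.ndarray, target_onehot: np.ndarray) -> Tensor:
    """Voxel-mean categorical cross-entropy with log-sum-exp stabilization."""
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    target_onehot = np.asarray(target_onehot, dtype=np.float32)
    _check_shapes(logits, target_onehot)
    logp = log_softmax(logits, axis=0)
    n_vox = int(np.prod(logits.data.shape[1:]))
    return tsum(Tensor(target_onehot) * logp) * (-1.0 / n_vox)


def dice_loss(logits: Tensor | np.ndarray, target_onehot: np.ndarray,
              eps: float = DICE_EPS) -> Tensor:
    """Soft Dice loss averaged over the three foreground classes.

    Per class c: 1 − (2 Σ x_c x̂_c + ε) / (Σ x_c + Σ x̂_c + ε), with x̂ the
    softmax probabilities.  ε smooths both numerator and denominator so a
    class absent from both prediction and target contributes zero loss.
    """
    logits = logits if isinstance(logits, Tensor) else Tensor(logits)
    target_onehot = np.asarray(target_onehot, dtype=np.float32)
    _check_shapes(logits, target_onehot)
    probs = exp(log_softmax(logits, axis=0))
    target = Tensor(target_onehot)
    total = None
    for c in FOREGROUND_CLASSES:
        p_c = _take_channel(probs, c)
        t_c = Tensor(target_onehot[c])
        inter = tsum(p_c * t_c)
        denom = tsum(t_c) + tsum(p_c)
        term = 1.0 - (2.0 * inter + eps) / (denom + eps)
        total = term if total is None else total + term
    return total * (1.0 / len(FOREGROUND_CLASSES))


def _take_channel(t: Tensor, c: int) -> Tensor:
    from .autodiff import _make  # narrow slice op, local to the loss

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[c] = g
            t._accumulate(full)

    return _make(t.data[c], (t,), backward)


def composite_loss(stage1_logits, stage2_logits, target_onehot: np.ndarray,
                   weights: LossWeights = LossWeights()) -> tuple[Tensor, LossReport]:
    """Joint two-stage objective; returns the differentiable total and a
    float breakdown for logging."""
    ce1 = cross_entropy(stage1_logits, target_onehot)
    ce2 = cross_entropy(stage2_logits, target_onehot)
    dc2 = dice_loss(stage2_logits, target_onehot)
    total = weights.w_ce1 * ce1 + weights.w_ce2 * ce2 + weights.w_dc2 * dc2
    report = LossReport(ce1=float(ce1.data), ce2=float(ce2.data),
                        dc2=float(dc2.data), total=float(total.data))
    return total, report
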