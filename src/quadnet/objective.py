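"""Four-task loss: interaction BCE, uncertainty, binding strength, type.

The network predicts, per protein pair, an interaction probability p, an
uncertainty score u, a binding strength s and a type distribution t.
The training objective is a weighted sum of four components:

* interaction — mean binary cross-entropy of p against the 0/1 label;
* uncertainty — mean of (+u) on correctly classified pairs and (−u) on
  misclassified ones, so the model learns low u where it is right and
  high u where it is wrong.  As written this term is unbounded below on
  a persistently wrong pair, so u is capped at ``u_max`` upstream (in
  the softplus head); the cap keeps the ordering incentive intact while
  making optimisation well-posed;
* binding strength — mean squared error of s against the
  confidence-derived target 2·|p − 0.5|·y.  The target is a constant
  (no gradient flows through it into p): a target that moved with the
  prediction would collapse the regression;
* type — cross-entropy when type labels exist, otherwise a KL pull of
  t toward the uniform distribution (the default, since binary PPI
  tables carry no type annotation).

All functions accept either autodiff tensors (for training) or plain
arrays (for analysis); plain-array inputs return Python floats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "interaction_loss",
    "predicted_label",
    "uncertainty_loss",
    "binding_strength_target",
    "binding_loss",
    "type_loss",
    "total_loss",
]

_P_CLIP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Component weights (λ1..λ4); the interaction task dominates."""

    interact: float = 1.0
    uncertainty: float = 0.1
    binding: float = 0.1
    type: float = 0.1

    def __post_init__(self):
        vals = (self.interact, self.uncertainty, self.binding, self.type)
        if any(v < 0 for v in vals):
            raise ValueError("loss weights must be nonnegative")
        if all(v == 0 for v in vals):
            raise ValueError("at least one loss weight must be positive")


@dataclass
class LossBreakdown:
    interact: float
    uncertainty: float
    binding: float
    type: float
    total: float
    n: int


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _maybe_float(t: Tensor, keep: bool):
    return t if keep else float(t.data)


def interaction_loss(p, y):
    """Mean binary cross-entropy; probabilities clipped away from {0, 1}."""
    pt, keep = _wrap(p)
    y = np.asarray(y, dtype=np.float64)
    if pt.data.shape != y.shape:
        raise ValueError(f"length mismatch: p {pt.data.shape} vs y {y.shape}")
    pc = pt.clip(_P_CLIP, 1.0 - _P_CLIP)
    yt = Tensor(y)
    loss = -(yt * pc.log() + (1.0 - yt) * (1.0 - pc).log()).mean()
    return _maybe_float(loss, keep)


def predicted_label(p) -> np.ndarray:
    """Hard label: 1 iff p is strictly greater than 0.5."""
    p = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    return (p > 0.5).astype(np.int64)


def uncertainty_loss(u, p, y):
    """Mean of +u on correct pairs and −u on misclassified pairs."""
    ut, keep = _wrap(u)
    if np.any(ut.data < 0):
        raise ValueError("uncertainty values must be nonnegative (softplus head)")
    y = np.asarray(y, dtype=np.int64)
    sign = np.where(predicted_label(p) == y, 1.0, -1.0)
    loss = (ut * Tensor(sign)).mean()
    return _maybe_float(loss, keep)


def binding_strength_target(p, y) -> np.ndarray:
    """Confidence-derived target 2·|p − 0.5|·y, detached from the graph."""
    p = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    return 2.0 * np.abs(p - 0.5) * y


def binding_loss(s, s_target):
    """Mean squared error of predicted binding strength vs its target."""
    st, keep = _wrap(s)
    target = np.asarray(s_target, dtype=np.float64)
    if st.data.shape != target.shape:
        raise ValueError(f"length mismatch: s {st.data.shape} vs target {target.shape}")
    diff = st - Tensor(target)
    return _maybe_float((diff * diff).mean(), keep)


def type_loss(t, y_type=None, *, n_types: int | None = None):
    """Cross-entropy against labels, or KL(t ‖ uniform) when unlabeled."""
    tt, keep = _wrap(t)
    rows = tt.data
    if rows.ndim != 2:
        raise ValueError(f"type distributions must be 2-D, got shape {rows.shape}")
    if np.any(np.abs(rows.sum(axis=1) - 1.0) > 1e-5):
        raise ValueError("type distribution rows must sum to 1 (within 1e-5)")
    n_classes = rows.shape[1]
    if n_types is not None and n_types != n_classes:
        raise ValueError(f"n_types {n_types} != distribution width {n_classes}")
    tc = tt.clip(_P_CLIP, None)
    if y_type is None:
        # KL(t ‖ u) = sum_c t_c (log t_c − log(1/C)), averaged over pairs
        kl = (tt * (tc.log() - np.log(1.0 / n_classes))).sum(axis=1).mean()
        return _maybe_float(kl, keep)
    y_type = np.asarray(y_type, dtype=np.int64)
    onehot = np.zeros_like(rows)
    onehot[np.arange(len(y_type)), y_type] = 1.0
    ce = -(Tensor(onehot) * tc.log()).sum(axis=1).mean()
    return _maybe_float(ce, keep)


def total_loss(p, u, s, t, y, weights: LossWeights = LossWeights(), y_type=None):
    """Weighted sum of the four components.

    Returns ``(loss, breakdown)`` where ``loss`` is a Tensor when the
    head outputs are tensors (so it can be backpropagated) and a float
    otherwise; ``breakdown`` always carries plain floats.
    """
    keep = isinstance(p, Tensor)
    l_int = interaction_loss(p, y)
    l_unc = uncertainty_loss(u, p, y)
    l_bind = binding_loss(s, binding_strength_target(p, y))
    l_type = type_loss(t, y_type)
    total = (
        weights.interact * l_int
        + weights.uncertainty * l_unc
        + weights.binding * l_bind
        + weights.type * l_type
    )
    breakdown = LossBreakdown(
        interact=float(l_int),
        uncertainty=float(l_unc),
        binding=float(l_bind),
        type=float(l_type),
        total=float(total),
        n=len(np.asarray(y)),
    )
    return (total, breakdown) if keep else (float(total), breakdown)
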