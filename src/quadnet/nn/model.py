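"""The quad-stream attention network for protein-pair classification.

Each protein pair is represented by four vectors — the two scaled
embeddings plus their element-wise product and absolute difference.
Every vector passes through its own attention block, the streams
exchange information through bidirectional cross-attention (protein 1
with protein 2, product with difference), the four states are fused by
a two-layer GELU network, and four task heads read off the fused state:

* ``p``  — interaction probability (sigmoid),
* ``u``  — prediction uncertainty (softplus, capped at ``u_max``),
* ``s``  — binding strength (sigmoid),
* ``t``  — interaction-type distribution (softmax over ``n_types``).

Multi-head attention as printed operates on a flat hidden vector, which
has no sequence axis; with a length-1 sequence, attention degenerates
to a linear map.  The default here factors each hidden vector into
``n_tokens`` tokens of ``hidden_dim / n_tokens`` channels, so attention
mixes channel groups.  Set ``n_tokens=1`` for the literal flat-vector
reading; both modes are exercised in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from .layers import Dropout, LayerNorm, Linear, Module, MultiHeadAttention

__all__ = ["ModelConfig", "AttentionBlock", "QuadNet", "TaskOutputs", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``hidden_dim`` must be divisible by ``n_tokens``, and the resulting
    per-token channel count by ``num_heads``.
    """

    input_dim: int
    hidden_dim: int = 256
    num_heads: int = 8
    n_tokens: int = 8
    ffn_expansion: int = 4
    dropout: float = 0.1
    n_types: int = 4
    u_max: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if self.hidden_dim % self.n_tokens != 0:
            raise ValueError(
                f"hidden_dim {self.hidden_dim} not divisible by n_tokens {self.n_tokens}"
            )
        token_dim = self.hidden_dim // self.n_tokens
        if token_dim % self.num_heads != 0:
            raise ValueError(
                f"token dim {token_dim} not divisible by num_heads {self.num_heads}"
            )
        if token_dim // self.num_heads < 1:
            raise ValueError("d_k would be < 1; reduce num_heads or n_tokens")

    @property
    def token_dim(self) -> int:
        return self.hidden_dim // self.n_tokens


@dataclass
class TaskOutputs:
    """Per-pair predictions from the four heads (autodiff tensors)."""

    p: Tensor  # (B,) interaction probability in (0, 1)
    u: Tensor  # (B,) uncertainty in [0, u_max]
    s: Tensor  # (B,) binding strength in (0, 1)
    t: Tensor  # (B, C) type distribution on the simplex

    def detach_arrays(self) -> dict[str, np.ndarray]:
        return {
            "p": self.p.data.copy(),
            "u": self.u.data.copy(),
            "s": self.s.data.copy(),
            "t": self.t.data.copy(),
        }


class AttentionBlock(Module):
    """Project -> LayerNorm -> gated multi-head self-attention -> FFN.

    The attention branch enters through a learnable scalar gate ``alpha``
    initialised at zero, so the block starts as an identity-plus-FFN map
    and learns how much attention to admit.
    """

    def __init__(self, input_dim: int, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_proj = Linear(input_dim, cfg.hidden_dim, rng)
        self.ln1 = LayerNorm(cfg.hidden_dim)
        self.attn = MultiHeadAttention(cfg.token_dim, cfg.num_heads, rng)
        self.alpha = Tensor(np.zeros(()), requires_grad=True)
        self.attn_dropout = Dropout(cfg.dropout, rng)
        self.ln2 = LayerNorm(cfg.hidden_dim)
        self.ffn_in = Linear(cfg.hidden_dim, cfg.ffn_expansion * cfg.hidden_dim, rng)
        self.ffn_dropout = Dropout(cfg.dropout, rng)
        self.ffn_out = Linear(cfg.ffn_expansion * cfg.hidden_dim, cfg.hidden_dim, rng)

    def _tokens(self, h: Tensor) -> Tensor:
        batch = h.shape[0]
        return h.reshape(batch, self.cfg.n_tokens, self.cfg.token_dim)

    def _flat(self, tokens: Tensor) -> Tensor:
        batch = tokens.shape[0]
        return tokens.reshape(batch, self.cfg.hidden_dim)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 2 or x.shape[1] != self.in_proj.W.shape[0]:
            raise ValueError(
                f"expected input (batch, {self.in_proj.W.shape[0]}), got {x.shape}"
            )
        h = self.in_proj(x)
        h_norm = self.ln1(h)
        tokens = self._tokens(h_norm)
        a = self._flat(self.attn(tokens, tokens, tokens))
        h_attn = h + self.alpha * self.attn_dropout(a)
        h_norm2 = self.ln2(h_attn)
        h_ff = self.ffn_out(self.ffn_dropout(self.ffn_in(h_norm2).gelu()))
        return h_attn + h_ff


class QuadNet(Module):
    """Four attention streams, cross-attention exchange, fusion, heads."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.block_p1 = AttentionBlock(cfg.input_dim, cfg, rng)
        self.block_p2 = AttentionBlock(cfg.input_dim, cfg, rng)
        self.block_int = AttentionBlock(cfg.input_dim, cfg, rng)
        self.block_diff = AttentionBlock(cfg.input_dim, cfg, rng)
        # bidirectional exchanges: protein 1 <-> protein 2, product <-> difference
        self.cross_12 = MultiHeadAttention(cfg.token_dim, cfg.num_heads, rng)
        self.cross_21 = MultiHeadAttention(cfg.token_dim, cfg.num_heads, rng)
        self.cross_id = MultiHeadAttention(cfg.token_dim, cfg.num_heads, rng)
        self.cross_di = MultiHeadAttention(cfg.token_dim, cfg.num_heads, rng)
        self.fuse1 = Linear(4 * cfg.hidden_dim, 2 * cfg.hidden_dim, rng)
        self.fuse2 = Linear(2 * cfg.hidden_dim, cfg.hidden_dim, rng)
        self.head_interact = Linear(cfg.hidden_dim, 1, rng)
        self.head_uncertainty = Linear(cfg.hidden_dim, 1, rng)
        self.head_binding = Linear(cfg.hidden_dim, 1, rng)
        self.head_type = Linear(cfg.hidden_dim, cfg.n_types, rng)
        self._training = False

    # dropout layers need to know the phase
    def train_mode(self, on: bool = True) -> "QuadNet":
        self._training = on
        for attr in vars(self).values():
            if isinstance(attr, AttentionBlock):
                attr.attn_dropout.training = on
                attr.ffn_dropout.training = on
        return self

    def eval_mode(self) -> "QuadNet":
        return self.train_mode(False)

    # -- forward pieces ---------------------------------------------------

    def _tokens(self, h: Tensor) -> Tensor:
        return h.reshape(h.shape[0], self.cfg.n_tokens, self.cfg.token_dim)

    def _flat(self, tokens: Tensor) -> Tensor:
        return tokens.reshape(tokens.shape[0], self.cfg.hidden_dim)

    def cross_exchange(
        self, h1: Tensor, h2: Tensor, h_int: Tensor, h_diff: Tensor
    ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        """Bidirectional cross-attention with residual connections."""
        t1, t2 = self._tokens(h1), self._tokens(h2)
        ti, td = self._tokens(h_int), self._tokens(h_diff)
        h1_cross = self._flat(self.cross_12(t1, t2, t2))
        h2_cross = self._flat(self.cross_21(t2, t1, t1))
        hi_cross = self._flat(self.cross_id(ti, td, td))
        hd_cross = self._flat(self.cross_di(td, ti, ti))
        return h1 + h1_cross, h2 + h2_cross, h_int + hi_cross, h_diff + hd_cross

    def fuse(self, h1: Tensor, h2: Tensor, h_int: Tensor, h_diff: Tensor) -> Tensor:
        h_concat = concat([h1, h2, h_int, h_diff], axis=-1)
        return self.fuse2(self.fuse1(h_concat).gelu()).gelu()

    def heads(self, h_fused: Tensor) -> TaskOutputs:
        batch = h_fused.shape[0]
        p = self.head_interact(h_fused).reshape(batch).sigmoid()
        u = self.head_uncertainty(h_fused).reshape(batch).softplus().clip(None, self.cfg.u_max)
        s = self.head_binding(h_fused).reshape(batch).sigmoid()
        t = self.head_type(h_fused).softmax(axis=-1)
        return TaskOutputs(p=p, u=u, s=s, t=t)

    def __call__(self, x1, x2, x_int, x_diff) -> TaskOutputs:
        x1, x2 = _as_tensor(x1), _as_tensor(x2)
        x_int, x_diff = _as_tensor(x_int), _as_tensor(x_diff)
        h1 = self.block_p1(x1)
        h2 = self.block_p2(x2)
        h_int = self.block_int(x_int)
        h_diff = self.block_diff(x_diff)
        h1, h2, h_int, h_diff = self.cross_exchange(h1, h2, h_int, h_diff)
        return self.heads(self.fuse(h1, h2, h_int, h_diff))

    def predict_proba(self, x1, x2, x_int, x_diff) -> np.ndarray:
        """Interaction probabilities with dropout off (deterministic)."""
        was_training = self._training
        self.eval_mode()
        try:
            return self(x1, x2, x_int, x_diff).p.data.copy()
        finally:
            self.train_mode(was_training)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64)))


def save_checkpoint(model: QuadNet, path: str | Path) -> None:
    """Write parameters (npz) plus a JSON config manifest alongside."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    manifest = asdict(model.cfg)
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> QuadNet:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    model = QuadNet(ModelConfig(**manifest))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
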