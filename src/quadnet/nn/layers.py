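"""Building blocks: modules, linear layers, layer norm, multi-head attention."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "MultiHeadAttention", "Dropout"]


class Module:
    """Lightweight parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = ""):
        for attr, value in vars(self).items():
            name = f"{prefix}{attr}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix=name + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()


class Linear(Module):
    """Affine map ``x @ W + b`` with Glorot-uniform initialisation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        bound = np.sqrt(6.0 / (in_dim + out_dim))
        self.W = Tensor(rng.uniform(-bound, bound, size=(in_dim, out_dim)), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class LayerNorm(Module):
    """Normalise over the last axis with learnable gain and shift."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        normed = centred * ((var + self.eps) ** -0.5)
        return normed * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity when the model is in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self.training = False

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class MultiHeadAttention(Module):
    """Scaled dot-product attention with ``num_heads`` parallel heads.

    Queries may come from a different token sequence than keys/values,
    which is how the cross-attention exchange between streams is built.
    The most recent attention weights are kept on ``last_weights`` (a
    plain array, outside the autodiff graph) so tests can inspect the
    row-stochastic structure.
    """

    def __init__(self, token_dim: int, num_heads: int, rng: np.random.Generator):
        if token_dim % num_heads != 0:
            raise ValueError(
                f"token_dim {token_dim} not divisible by num_heads {num_heads}"
            )
        self.num_heads = num_heads
        self.d_k = token_dim // num_heads
        self.wq = Linear(token_dim, token_dim, rng)
        self.wk = Linear(token_dim, token_dim, rng)
        self.wv = Linear(token_dim, token_dim, rng)
        self.wo = Linear(token_dim, token_dim, rng)
        self.last_weights: np.ndarray | None = None

    def _split_heads(self, x: Tensor) -> Tensor:
        batch, tokens, _ = x.shape
        return x.reshape(batch, tokens, self.num_heads, self.d_k).transpose((0, 2, 1, 3))

    def __call__(self, query: Tensor, key: Tensor, value: Tensor) -> Tensor:
        if query.shape[-1] != key.shape[-1] or key.shape != value.shape:
            raise ValueError(
                f"incompatible attention shapes: Q{query.shape} K{key.shape} V{value.shape}"
            )
        q = self._split_heads(self.wq(query))  # (B, H, Tq, d_k)
        k = self._split_heads(self.wk(key))  # (B, H, Tk, d_k)
        v = self._split_heads(self.wv(value))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        weights = scores.softmax(axis=-1)  # rows sum to 1 over keys
        self.last_weights = weights.data.copy()
        mixed = weights @ v  # (B, H, Tq, d_k)
        batch, _, n_q, _ = mixed.shape
        merged = mixed.transpose((0, 2, 1, 3)).reshape(batch, n_q, self.num_heads * self.d_k)
        return self.wo(merged)
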