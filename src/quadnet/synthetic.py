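"""Synthetic embeddings and planted interaction rules for benchmarking.

Real protein-language-model embeddings are heavy-tailed and carry
outliers (rare proteins, unusual motifs, disordered regions), which is
what motivates robust median/IQR scaling downstream.  The generator
emulates exactly those two properties and nothing more:

* per-coordinate draws from a Student-t with few degrees of freedom
  (``tail_df``, default 3), rescaled to unit variance, so kurtosis is
  well above Gaussian and extreme values occur at realistic rates;
* a planted symmetric bilinear rule score(a, b) = aᵀ S b with S a
  rank-``rule_rank`` symmetric matrix, thresholded at the empirical
  quantile that yields the requested positive fraction.  A symmetric
  bilinear rule puts signal into both the element-wise product and the
  absolute difference of a pair, so all four model streams see
  label-relevant structure.

Everything is deterministic given ``seed``; the store, the rule and
the pair sample each use a fixed offset of the base seed so any stage
can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairs import PairTable
from .store import EmbeddingStore

__all__ = [
    "SyntheticSpec",
    "InteractionOracle",
    "generate_protein_embeddings",
    "plant_interaction_rule",
    "sample_pair_dataset",
]

# fixed seed offsets per artifact; kept below 2**31 by the modulus
_SEED_STORE, _SEED_RULE, _SEED_PAIRS = 0, 1, 2
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    ``dim`` defaults to the 1024 dimensions of the intended real
    embeddings; tests reduce it freely.
    """

    n_proteins: int
    dim: int = 1024
    tail_df: float = 3.0
    rule_rank: int = 4
    label_noise: float = 0.0
    pos_frac: float = 0.5
    seed: int = 0
    n_calibration_pairs: int = 20_000

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if self.dim < 1:
            raise ValueError(f"dim must be >= 1, got {self.dim}")
        if self.tail_df <= 2:
            raise ValueError(f"tail_df must be > 2 for finite variance, got {self.tail_df}")
        if self.rule_rank < 1:
            raise ValueError(f"rule_rank must be >= 1, got {self.rule_rank}")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError(f"label_noise must be in [0, 0.5), got {self.label_noise}")
        if not 0 < self.pos_frac < 1:
            raise ValueError(f"pos_frac must be in (0, 1), got {self.pos_frac}")

    def _rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng((self.seed + offset) % _SEED_MOD)


@dataclass(frozen=True)
class InteractionOracle:
    """Symmetric bilinear scorer with a calibrated decision threshold."""

    S: np.ndarray  # symmetric (dim, dim), rank <= rule_rank
    tau: float

    def score(self, a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        return np.einsum("...i,ij,...j->...", a, self.S, b)

    def label(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return (np.asarray(self.score(a, b)) > self.tau).astype(np.int64)


def generate_protein_embeddings(spec: SyntheticSpec) -> EmbeddingStore:
    """Heavy-tailed embedding vectors with identifiers P000001, P000002, ..."""
    rng = spec._rng(_SEED_STORE)
    raw = rng.standard_t(spec.tail_df, size=(spec.n_proteins, spec.dim))
    # unit-variance rescale so tail_df changes tail weight, not scale
    raw /= np.sqrt(spec.tail_df / (spec.tail_df - 2.0))
    ids = [f"P{i + 1:06d}" for i in range(spec.n_proteins)]
    return EmbeddingStore(ids, raw)


def plant_interaction_rule(store: EmbeddingStore, spec: SyntheticSpec) -> InteractionOracle:
    """Draw a rank-r symmetric bilinear rule and calibrate its threshold.

    The threshold is the empirical (1 − pos_frac) quantile of scores on
    a seeded sample of distinct pairs, so the planted positive rate
    matches ``pos_frac`` up to sampling error.
    """
    if len(store) < 2:
        raise ValueError("need at least 2 proteins to plant a pairwise rule")
    if spec.rule_rank > spec.dim:
        raise ValueError(
            f"rule_rank {spec.rule_rank} exceeds embedding dim {spec.dim}"
        )
    rng = spec._rng(_SEED_RULE)
    # rank-r symmetric rule S = sum_k lambda_k v_k v_k^T with alternating
    # signs (so scores are two-sided) and axis-concentrated directions:
    # each v_k is a coordinate spike plus a small dense component, which
    # keeps most of the score variance in the diagonal of S — i.e. in
    # the element-wise product feature — so the planted classes stay
    # separable by the pair features the model actually consumes.
    spike_coords = rng.choice(spec.dim, size=spec.rule_rank, replace=False)
    dense_mix = 0.05
    S = np.zeros((spec.dim, spec.dim))
    for k, j in enumerate(spike_coords):
        g = rng.standard_normal(spec.dim)
        g /= np.linalg.norm(g)
        v = np.sqrt(1.0 - dense_mix**2) * np.eye(spec.dim)[j] + dense_mix * g
        S += (-1.0) ** k * np.outer(v, v)
    S = 0.5 * (S + S.T)

    n_cal = spec.n_calibration_pairs
    i = rng.integers(0, len(store), size=n_cal)
    j = rng.integers(0, len(store), size=n_cal)
    distinct = i != j
    i, j = i[distinct], j[distinct]
    scores = np.einsum("ni,ij,nj->n", store.matrix[i], S, store.matrix[j])
    if np.ptp(scores) < 1e-12:
        raise ValueError("degenerate rule: all pair scores identical, cannot calibrate")
    tau = float(np.quantile(scores, 1.0 - spec.pos_frac))
    return InteractionOracle(S=S, tau=tau)


def _decode_pair(k: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear indices in [0, C(n,2)) to pairs (i, j), i < j."""
    # row i occupies indices [i*n - i*(i+1)/2, ...) — invert by quadratic formula
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8 * k)) / 2).astype(np.int64)
    offset = i * n - (i * (i + 1)) // 2
    j = (k - offset + i + 1).astype(np.int64)
    return i, j


def sample_pair_dataset(
    store: EmbeddingStore,
    oracle: InteractionOracle,
    n_pairs: int,
    seed: int,
    label_noise: float = 0.0,
) -> PairTable:
    """Sample distinct unordered pairs and label them with the oracle.

    Labels are flipped independently with probability ``label_noise``.
    """
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    if not 0 <= label_noise < 0.5:
        raise ValueError(f"label_noise must be in [0, 0.5), got {label_noise}")
    n = len(store)
    total = n * (n - 1) // 2
    if n_pairs > total:
        raise ValueError(
            f"requested {n_pairs} pairs but only {total} distinct unordered pairs exist"
        )
    rng = np.random.default_rng((seed + _SEED_PAIRS) % _SEED_MOD)
    if total <= 5_000_000:
        chosen = rng.choice(total, size=n_pairs, replace=False)
    else:  # rejection sampling keeps memory bounded for huge pair spaces
        seen: set[int] = set()
        while len(seen) < n_pairs:
            for k in rng.integers(0, total, size=n_pairs):
                seen.add(int(k))
                if len(seen) == n_pairs:
                    break
        chosen = np.fromiter(seen, dtype=np.int64)
        rng.shuffle(chosen)
        chosen = chosen[:n_pairs]
    i, j = _decode_pair(chosen.astype(np.float64), n)
    labels = oracle.label(store.matrix[i], store.matrix[j])
    if label_noise > 0:
        flips = rng.random(n_pairs) < label_noise
        labels = np.where(flips, 1 - labels, labels)
    ids = np.array(store.identifiers)
    return PairTable.from_arrays(ids[i], ids[j], labels)
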