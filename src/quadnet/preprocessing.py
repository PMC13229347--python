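"""Robust scaling, pair feature construction, and noise augmentation.

Embedding matrices are normalised per dimension by median and
interquartile range, X_scaled = (X − median(X)) / IQR(X), which is
stable under the heavy tails and outliers typical of language-model
embeddings (mean/std scaling is not).  Quantiles use the
linear-interpolation ("type 7") convention, recorded in the persisted
scaler manifest.  Dimensions with essentially zero spread get an IQR of
1, i.e. they are centred but left unscaled.

Per pair, the model consumes four vectors built from the two scaled
embeddings x1, x2:

    x_int  = x1 ⊙ x2     (synergistic activation, order-symmetric)
    x_diff = |x1 − x2|   (complementary activation, order-symmetric)

During training, independent Gaussian noise N(0, σ²I) with σ = 0.02 is
added to x1 and x2 — resampled every epoch — before the product and
difference are formed, so the derived features see the perturbed
inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .store import EmbeddingStore

__all__ = [
    "ScalerParams",
    "AugmentationSpec",
    "FeatureBundle",
    "fit_robust_scaler",
    "transform_robust",
    "interaction_product",
    "absolute_difference",
    "augment_gaussian",
    "assemble_features",
    "assemble_feature_matrices",
]

IQR_FLOOR = 1e-8


@dataclass
class ScalerParams:
    median: np.ndarray
    iqr: np.ndarray  # effective divisor: floored dimensions already set to 1
    iqr_floor: float = IQR_FLOOR
    quantile_convention: str = "linear"

    @property
    def dim(self) -> int:
        return len(self.median)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "median": self.median.tolist(),
                    "iqr": self.iqr.tolist(),
                    "iqr_floor": self.iqr_floor,
                    "quantile_convention": self.quantile_convention,
                }
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            median=np.asarray(payload["median"], dtype=np.float64),
            iqr=np.asarray(payload["iqr"], dtype=np.float64),
            iqr_floor=payload["iqr_floor"],
            quantile_convention=payload["quantile_convention"],
        )


@dataclass
class AugmentationSpec:
    """Gaussian perturbation of the scaled embeddings (training only)."""

    sigma: float = 0.02
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        self._rng = np.random.default_rng(self.seed)


@dataclass
class FeatureBundle:
    """The four model inputs for one protein pair."""

    x1: np.ndarray
    x2: np.ndarray
    x_int: np.ndarray
    x_diff: np.ndarray


def fit_robust_scaler(X_train: np.ndarray) -> ScalerParams:
    """Per-dimension median and IQR of the training matrix."""
    X_train = np.asarray(X_train, dtype=np.float64)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError(
            f"need a 2-D matrix with at least 2 rows, got shape {X_train.shape}"
        )
    median = np.median(X_train, axis=0)
    q1 = np.quantile(X_train, 0.25, axis=0, method="linear")
    q3 = np.quantile(X_train, 0.75, axis=0, method="linear")
    iqr = q3 - q1
    iqr = np.where(iqr < IQR_FLOOR, 1.0, iqr)
    return ScalerParams(median=median, iqr=iqr)


def transform_robust(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.shape[-1] != params.dim:
        raise ValueError(
            f"dimension mismatch: data has {X.shape[-1]} columns, scaler fitted on {params.dim}"
        )
    return (X - params.median) / params.iqr


def interaction_product(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Element-wise product; large where both proteins activate together."""
    x1, x2 = np.asarray(x1, dtype=np.float64), np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    return x1 * x2


def absolute_difference(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Element-wise |x1 − x2|; the per-dimension contrast between the pair."""
    x1, x2 = np.asarray(x1, dtype=np.float64), np.asarray(x2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    return np.abs(x1 - x2)


def augment_gaussian(x: np.ndarray, spec: AugmentationSpec) -> np.ndarray:
    """Add a fresh N(0, σ²I) draw; exact identity when σ = 0."""
    x = np.asarray(x, dtype=np.float64)
    if spec.sigma == 0.0:
        return x.copy()
    return x + spec._rng.normal(0.0, spec.sigma, size=x.shape)


def assemble_features(
    pair: tuple[str, str],
    store: EmbeddingStore,
    scaler: ScalerParams,
    augmentation: AugmentationSpec | None = None,
) -> FeatureBundle:
    """Look up, scale, optionally perturb, then derive the pair features."""
    a, b = pair
    x1 = transform_robust(store.vector(a), scaler)
    x2 = transform_robust(store.vector(b), scaler)
    if augmentation is not None:
        x1 = augment_gaussian(x1, augmentation)
        x2 = augment_gaussian(x2, augmentation)
    return FeatureBundle(
        x1=x1, x2=x2, x_int=interaction_product(x1, x2), x_diff=absolute_difference(x1, x2)
    )


def assemble_feature_matrices(
    pairs_a,
    pairs_b,
    store: EmbeddingStore,
    scaler: ScalerParams,
    augmentation: AugmentationSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised variant over many pairs: (X1, X2, X_int, X_diff)."""
    x1 = transform_robust(store.rows(pairs_a), scaler)
    x2 = transform_robust(store.rows(pairs_b), scaler)
    if augmentation is not None:
        x1 = augment_gaussian(x1, augmentation)
        x2 = augment_gaussian(x2, augmentation)
    return x1, x2, x1 * x2, np.abs(x1 - x2)
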