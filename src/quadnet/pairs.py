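"""Interaction-pair tables: dedup, class balancing, stratified splitting.

A pair table holds records (protein_a, protein_b, label) with binary
labels (1 = interacting).  Pairs are unordered: the canonical form puts
the lexicographically smaller identifier first, and deduplication keeps
one record per unordered pair.  Splitting is two-stage stratified: the
test partition is carved out first, then validation is separated from
training, each stage preserving the class proportions.

Balancing before splitting (the default pipeline order when a table is
oversampled upstream) can place copies of one duplicated record on both
sides of a split boundary; :func:`audit_leakage` counts exactly those
crossings so the effect is measured rather than silent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PairTable",
    "SplitSizes",
    "DatasetSplits",
    "canonicalize_and_dedup",
    "balance_by_undersampling",
    "balance_by_oversampling",
    "compute_split_sizes",
    "two_stage_stratified_split",
    "audit_leakage",
]

_COLUMNS = ["protein_a", "protein_b", "label"]


class PairTable:
    """Thin wrapper over a DataFrame with columns protein_a/protein_b/label."""

    def __init__(self, frame: pd.DataFrame):
        if list(frame.columns) != _COLUMNS:
            raise ValueError(f"expected columns {_COLUMNS}, got {list(frame.columns)}")
        labels = frame["label"].to_numpy()
        if not np.isin(labels, [0, 1]).all():
            raise ValueError("labels must be 0 or 1")
        self.frame = frame.reset_index(drop=True).astype(
            {"protein_a": str, "protein_b": str, "label": np.int64}
        )

    @classmethod
    def from_arrays(cls, a, b, labels) -> "PairTable":
        return cls(pd.DataFrame({"protein_a": a, "protein_b": b, "label": labels}))

    @classmethod
    def from_records(cls, records) -> "PairTable":
        return cls(pd.DataFrame(records, columns=_COLUMNS))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_pos(self) -> int:
        return int((self.frame["label"] == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.frame["label"] == 0).sum())

    @property
    def pos_frac(self) -> float:
        return self.n_pos / len(self) if len(self) else float("nan")

    def canonical_keys(self) -> pd.Series:
        """Order-normalised pair keys 'min||max' for dedup and audits."""
        a, b = self.frame["protein_a"], self.frame["protein_b"]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        return lo.str.cat(hi, sep="||")

    # -- IO ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str}))


@dataclass(frozen=True)
class SplitSizes:
    n_train: int
    n_val: int
    n_test: int
    test_frac: float = 0.12
    val_frac_total: float = 0.20

    @property
    def n_total(self) -> int:
        return self.n_train + self.n_val + self.n_test


@dataclass
class DatasetSplits:
    train: PairTable
    val: PairTable
    test: PairTable
    seed: int
    sizes: SplitSizes

    def manifest(self) -> dict:
        audit = audit_leakage(self)
        return {
            "seed": self.seed,
            "test_frac": self.sizes.test_frac,
            "val_frac_total": self.sizes.val_frac_total,
            "sizes": {
                "train": len(self.train),
                "val": len(self.val),
                "test": len(self.test),
            },
            "class_counts": {
                name: {"pos": part.n_pos, "neg": part.n_neg}
                for name, part in [("train", self.train), ("val", self.val), ("test", self.test)]
            },
            "leakage": audit,
        }

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.train.to_tsv(out_dir / "train.tsv")
        self.val.to_tsv(out_dir / "val.tsv")
        self.test.to_tsv(out_dir / "test.tsv")
        (out_dir / "split_manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def canonicalize_and_dedup(pairs: PairTable) -> PairTable:
    """Keep one record per unordered pair, order-normalised.

    The first occurrence's label is kept.  If the same unordered pair
    appears with both labels, there is no principled winner, so the
    conflicting pairs are reported and the call refuses.
    """
    frame = pairs.frame.copy()
    a, b = frame["protein_a"], frame["protein_b"]
    frame["protein_a"], frame["protein_b"] = np.minimum(a, b), np.maximum(a, b)
    key = frame["protein_a"].str.cat(frame["protein_b"], sep="||")
    conflict_mask = frame.groupby(key)["label"].transform("nunique") > 1
    if conflict_mask.any():
        offenders = sorted(key[conflict_mask].unique())
        raise ValueError(
            "conflicting labels for unordered pairs: "
            + ", ".join(k.replace("||", "-") for k in offenders[:20])
            + ("" if len(offenders) <= 20 else f" (+{len(offenders) - 20} more)")
        )
    deduped = frame.loc[~key.duplicated(keep="first")]
    return PairTable(deduped[_COLUMNS])


def _require_both_classes(pairs: PairTable) -> None:
    if pairs.n_pos == 0 or pairs.n_neg == 0:
        raise ValueError(
            f"both classes must be nonempty (got {pairs.n_pos} positive, {pairs.n_neg} negative)"
        )


def balance_by_undersampling(pairs: PairTable, seed: int) -> PairTable:
    """Subsample the majority class (without replacement) to the minority count."""
    _require_both_classes(pairs)
    rng = np.random.default_rng(seed)
    frame = pairs.frame
    target = min(pairs.n_pos, pairs.n_neg)
    parts = []
    for label in (0, 1):
        cls = frame[frame["label"] == label]
        if len(cls) > target:
            cls = cls.iloc[np.sort(rng.choice(len(cls), size=target, replace=False))]
        parts.append(cls)
    return PairTable(pd.concat(parts, ignore_index=True)[_COLUMNS])


def balance_by_oversampling(pairs: PairTable, seed: int) -> PairTable:
    """Resample the minority class with replacement up to the majority count.

    Every original record is retained; only the shortfall is drawn.
    """
    _require_both_classes(pairs)
    rng = np.random.default_rng(seed)
    frame = pairs.frame
    target = max(pairs.n_pos, pairs.n_neg)
    parts = []
    for label in (0, 1):
        cls = frame[frame["label"] == label]
        shortfall = target - len(cls)
        if shortfall > 0:
            extra = cls.iloc[rng.integers(0, len(cls), size=shortfall)]
            cls = pd.concat([cls, extra])
        parts.append(cls)
    return PairTable(pd.concat(parts, ignore_index=True)[_COLUMNS])


def compute_split_sizes(
    n_total: int, test_frac: float = 0.12, val_frac_total: float = 0.20
) -> SplitSizes:
    """Partition counts: test = ceil, validation = round-half-up, train = rest."""
    if not (0 < test_frac < 1 and 0 < val_frac_total < 1):
        raise ValueError("fractions must be in (0, 1)")
    if test_frac + val_frac_total >= 1:
        raise ValueError("test_frac + val_frac_total must be < 1")
    n_test = math.ceil(test_frac * n_total)
    n_val = math.floor(val_frac_total * n_total + 0.5)  # half-up
    n_train = n_total - n_test - n_val
    if n_train <= 0:
        raise ValueError(f"no training records left (n_total={n_total})")
    return SplitSizes(n_train, n_val, n_test, test_frac, val_frac_total)


def compute_split_sizes_nested(
    n_total: int, test_frac: float = 0.12, stage2_frac: float = 0.225
) -> SplitSizes:
    """Variant computing validation as a fraction of the post-test remainder."""
    n_test = math.ceil(test_frac * n_total)
    n_val = math.floor(stage2_frac * (n_total - n_test) + 0.5)
    n_train = n_total - n_test - n_val
    if n_train <= 0:
        raise ValueError(f"no training records left (n_total={n_total})")
    return SplitSizes(n_train, n_val, n_test, test_frac, stage2_frac * (1 - test_frac))


def _stratified_take(
    frame: pd.DataFrame, n_take: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split off ``n_take`` rows preserving label proportions.

    Per-class quotas are the exact proportional shares rounded down,
    with remainders assigned by largest fractional part (ties broken by
    label order) — deterministic and independent of row order.
    """
    labels = sorted(frame["label"].unique())
    counts = {c: int((frame["label"] == c).sum()) for c in labels}
    n_total = len(frame)
    exact = {c: n_take * counts[c] / n_total for c in labels}
    quota = {c: math.floor(exact[c]) for c in labels}
    short = n_take - sum(quota.values())
    for c in sorted(labels, key=lambda c: (-(exact[c] - quota[c]), c))[:short]:
        quota[c] += 1
    taken_parts, kept_parts = [], []
    for c in labels:
        cls = frame[frame["label"] == c]
        if quota[c] > counts[c]:
            raise ValueError(f"class {c} has too few records for the requested split")
        pick = np.zeros(len(cls), dtype=bool)
        pick[rng.choice(len(cls), size=quota[c], replace=False)] = True
        taken_parts.append(cls.iloc[pick])
        kept_parts.append(cls.iloc[~pick])
    taken = pd.concat(taken_parts).sort_index()
    kept = pd.concat(kept_parts).sort_index()
    return taken, kept


def two_stage_stratified_split(
    pairs: PairTable, sizes: SplitSizes, seed: int
) -> DatasetSplits:
    """Stage 1 isolates the test set; stage 2 separates validation.

    Each stage stratifies on the binary label, so rounding error in the
    class shares never compounds across the three partitions.
    """
    if sizes.n_total != len(pairs):
        raise ValueError(
            f"sizes computed for {sizes.n_total} records but table has {len(pairs)}"
        )
    for c in (0, 1):
        n_c = int((pairs.frame["label"] == c).sum())
        if 0 < n_c < 3:
            raise ValueError(
                f"class {c} has only {n_c} records; need at least one per split"
            )
    rng = np.random.default_rng(seed)
    test_frame, rest = _stratified_take(pairs.frame, sizes.n_test, rng)
    val_frame, train_frame = _stratified_take(rest, sizes.n_val, rng)
    return DatasetSplits(
        train=PairTable(train_frame[_COLUMNS]),
        val=PairTable(val_frame[_COLUMNS]),
        test=PairTable(test_frame[_COLUMNS]),
        seed=seed,
        sizes=sizes,
    )


def audit_leakage(splits: DatasetSplits) -> dict[str, int]:
    """Count canonical pair keys shared between split partitions.

    All counts are zero when splitting a deduplicated table; nonzero
    counts arise when oversampling duplicated records before splitting.
    """
    keys = {
        "train": set(splits.train.canonical_keys()),
        "val": set(splits.val.canonical_keys()),
        "test": set(splits.test.canonical_keys()),
    }
    return {
        "train_val": len(keys["train"] & keys["val"]),
        "train_test": len(keys["train"] & keys["test"]),
        "val_test": len(keys["val"] & keys["test"]),
    }
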