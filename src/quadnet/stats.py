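"""Nonparametric validation: 2×2 chi-square with effect sizes, exact Wilcoxon.

The chi-square test asks whether predicted and actual interaction
classes are associated: χ² = Σ (O − E)² / E with expected counts from
the row/column margins, df = 1 for a 2×2 table.  For a 2×2 table the
three usual effect sizes coincide: Cramér's V = φ = Cohen's w
= sqrt(χ² / n).  The Yates continuity correction is off by default (the
uncorrected statistic is what the formula above computes) and available
behind a flag.

The Wilcoxon signed-rank test uses the *exact* null distribution of
W⁺ (the sum of positive signed ranks), not a normal approximation:
under H0 each rank carries an independent random sign, so the
distribution of 2·W⁺ is the convolution of n two-point distributions
{0, 2r_i} — computed here on an integer half-rank grid, which also
handles average ranks from ties exactly.  Zero differences are dropped
before ranking (standard signed-rank convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "WilcoxonResult",
    "confusion_table",
    "chi_square_2x2",
    "wilcoxon_signed_rank_exact",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 observed counts, arranged [[TP, FN], [FP, TN]]:

    rows = actual class (1 then 0), columns = predicted (1 then 0).
    """

    observed: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.observed)
        if obs.shape != (2, 2):
            raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
        if np.any(obs < 0) or not np.issubdtype(obs.dtype, np.integer):
            raise ValueError("observed counts must be nonnegative integers")
        object.__setattr__(self, "observed", obs.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.observed.sum())


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    cramers_v: float
    phi: float
    cohens_w: float
    expected: np.ndarray


@dataclass(frozen=True)
class WilcoxonResult:
    W: float  # sum of positive ranks
    n_effective: int
    p_one_sided: float  # P(W+ >= observed) under H0
    p_two_sided: float


def confusion_table(predictions, labels) -> ContingencyTable:
    """Cross-tabulate binary predictions against binary labels."""
    yhat = np.asarray(predictions)
    y = np.asarray(labels)
    if yhat.shape != y.shape:
        raise ValueError(f"length mismatch: {yhat.shape} vs {y.shape}")
    if not (np.isin(yhat, [0, 1]).all() and np.isin(y, [0, 1]).all()):
        raise ValueError("predictions and labels must be binary (0/1)")
    tp = int(np.sum((yhat == 1) & (y == 1)))
    fn = int(np.sum((yhat == 0) & (y == 1)))
    fp = int(np.sum((yhat == 1) & (y == 0)))
    tn = int(np.sum((yhat == 0) & (y == 0)))
    return ContingencyTable(np.array([[tp, fn], [fp, tn]]))


def chi_square_2x2(
    table: ContingencyTable, continuity_correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square of independence on a 2×2 table, df = 1."""
    obs = table.observed.astype(np.float64)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row * col / n
    if np.any(expected == 0):
        raise ValueError("a margin is zero, expected counts undefined")
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    v = float(np.sqrt(stat / n))
    return ChiSquareResult(
        chi2=stat, df=1, p_value=p, cramers_v=v, phi=v, cohens_w=v, expected=expected
    )


def _exact_signed_rank_pmf(ranks: np.ndarray) -> np.ndarray:
    """PMF of 2·W⁺ under the random-sign null, on an integer grid.

    Doubling the (possibly half-integer average) ranks puts everything
    on integers; the pmf is built by convolving one two-point factor
    per observation.
    """
    units = np.rint(2.0 * ranks).astype(np.int64)
    pmf = np.zeros(units.sum() + 1)
    pmf[0] = 1.0
    top = 0
    for r in units:
        nxt = pmf.copy()
        nxt[r : top + r + 1] += pmf[: top + 1]
        pmf = 0.5 * nxt
        top += r
    return pmf


def wilcoxon_signed_rank_exact(differences) -> WilcoxonResult:
    """Exact signed-rank test on paired differences.

    One-sided p is the upper tail P(W⁺ ≥ W_obs) — small when the first
    member of each pair systematically exceeds the second.
    """
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    ranks = rankdata(np.abs(d))  # average ranks under ties
    w_pos = float(ranks[d > 0].sum())
    pmf = _exact_signed_rank_pmf(ranks)
    grid = np.arange(pmf.size)  # units of half-ranks
    w_units = int(np.rint(2.0 * w_pos))
    p_upper = float(pmf[grid >= w_units].sum())
    p_lower = float(pmf[grid <= w_units].sum())
    p_two = float(min(1.0, 2.0 * min(p_upper, p_lower)))
    return WilcoxonResult(
        W=w_pos, n_effective=int(d.size), p_one_sided=p_upper, p_two_sided=p_two
    )
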