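"""Concordance statistics between categorical classifiers.

Cohen's kappa (chance-corrected agreement for square tables) with a
large-sample confidence interval, and Cramér's V (chi-square-based
association for arbitrary r x c tables), plus the verbal interpretation
bands commonly used for clinical score comparisons.

Two computational choices matter and are deliberate:

* The kappa standard error is the simple large-sample form
  ``sqrt(po(1-po)) / ((1-pe) * sqrt(n))`` rather than the full
  Fleiss-Cohen-Everitt variance; clinical software commonly reports it,
  and on nested 2x2 classifier tables the two differ little.
* V uses the plain Pearson chi-square statistic with no continuity
  (Yates) correction and no bias correction.

``reconstruct_nested_2x2`` recovers the unique joint table of two binary
classifiers from their marginals when one classifier is strictly nested
in the other (stricter-positive implies laxer-positive), which pins the
off-diagonal cell at zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Optional, Sequence

import numpy as np
from scipy.stats import chi2_contingency


class DegenerateTableError(ValueError):
    """The table cannot support the requested statistic."""


class InsufficientDataError(ValueError):
    """Fewer than two usable observation pairs."""


@dataclass
class ContingencyTable:
    """Labelled r x c count matrix."""

    row_labels: list
    col_labels: list
    counts: np.ndarray
    dropped_pairs: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def is_square(self) -> bool:
        return list(self.row_labels) == list(self.col_labels)


def contingency(labels_a: Sequence[Optional[Hashable]],
                labels_b: Sequence[Optional[Hashable]],
                row_order: Optional[Sequence] = None,
                col_order: Optional[Sequence] = None) -> ContingencyTable:
    """Cross-tabulate two equal-length label sequences.

    Pairs where either label is None are dropped and counted in
    ``dropped_pairs``.  Label order defaults to order of first appearance.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    pairs = [(a, b) for a, b in zip(labels_a, labels_b)
             if a is not None and b is not None]
    dropped = len(labels_a) - len(pairs)
    if len(pairs) < 2:
        raise InsufficientDataError(
            f"only {len(pairs)} usable pairs after dropping missing labels")

    def ordered(seen: Sequence, explicit) -> list:
        if explicit is not None:
            return list(explicit)
        out: list = []
        for label in seen:
            if label not in out:
                out.append(label)
        return out

    rows = ordered([a for a, _ in pairs], row_order)
    cols = ordered([b for _, b in pairs], col_order)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for a, b in pairs:
        counts[rows.index(a), cols.index(b)] += 1
    return ContingencyTable(rows, cols, counts, dropped_pairs=dropped)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    po: float   # observed agreement proportion
    pe: float   # chance agreement proportion
    n: int


def cohen_kappa(table: ContingencyTable) -> KappaResult:
    """Cohen's kappa with a 95% large-sample confidence interval.

    Requires a square table over the same label set on both axes.
    """
    if not table.is_square():
        raise ValueError("kappa requires a square table over one label set")
    counts = table.counts.astype(float)
    n = counts.sum()
    if n == 0:
        raise DegenerateTableError("empty table")
    po = float(np.trace(counts) / n)
    pe = float((table.row_marginals / n) @ (table.col_marginals / n))
    if pe >= 1.0:
        raise DegenerateTableError("chance agreement is 1 (degenerate marginals)")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po)) / ((1 - pe) * math.sqrt(n))
    half = 1.959963984540054 * se
    return KappaResult(kappa=kappa, se=se, ci_low=kappa - half,
                       ci_high=kappa + half, po=po, pe=pe, n=int(n))


def cramer_v(table: ContingencyTable) -> float:
    """Cramér's V = sqrt(chi2 / (n * min(r-1, c-1))), plain Pearson chi2."""
    counts = table.counts
    r, c = counts.shape
    if r < 2 or c < 2:
        raise DegenerateTableError("V requires at least a 2x2 table")
    if table.n == 0:
        raise DegenerateTableError("empty table")
    if (table.row_marginals == 0).any() or (table.col_marginals == 0).any():
        raise DegenerateTableError("zero row or column marginal")
    chi2 = chi2_contingency(counts, correction=False)[0]
    return float(math.sqrt(chi2 / (table.n * min(r - 1, c - 1))))


class InfeasibleMarginalsError(ValueError):
    """Marginals incompatible with the nesting constraint."""


def reconstruct_nested_2x2(marginals_a: tuple[int, int],
                           marginals_b: tuple[int, int],
                           labels: tuple = ("benign", "malignant")) -> ContingencyTable:
    """Unique 2x2 joint table of nested binary classifiers from marginals.

    ``a`` is the laxer classifier, ``b`` the stricter one (rows), with
    b-positive implying a-positive, so cell (b-positive, a-negative) is
    zero and the remaining cells are forced:
    counts = [[b_neg-only overlap, a_pos & b_neg], [0, b_pos]].
    """
    a_neg, a_pos = marginals_a
    b_neg, b_pos = marginals_b
    if min(a_neg, a_pos, b_neg, b_pos) < 0:
        raise ValueError("negative marginal count")
    if a_neg + a_pos != b_neg + b_pos:
        raise InfeasibleMarginalsError("marginal totals differ")
    if b_pos > a_pos:
        raise InfeasibleMarginalsError(
            f"stricter classifier has more positives ({b_pos} > {a_pos})")
    counts = np.array([[a_neg, a_pos - b_pos], [0, b_pos]], dtype=np.int64)
    return ContingencyTable(list(labels), list(labels), counts)


# Verbal interpretation bands for kappa and V.  Upper bounds are
# inclusive; band edges follow the printed two-decimal conventions.
KAPPA_BANDS = (
    (0.20, "no agreement"),
    (0.39, "minimal agreement"),
    (0.59, "weak agreement"),
    (0.79, "moderate agreement"),
    (0.90, "strong agreement"),
    (1.00, "almost perfect agreement"),
)

V_BANDS = (
    (0.3, "weak association"),
    (0.6, "good association"),
    (1.0, "strong association"),
)


def interpret_kappa(kappa: float) -> str:
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa out of range: {kappa}")
    if kappa <= 0:
        return KAPPA_BANDS[0][1]
    for upper, band in KAPPA_BANDS:
        if round(kappa, 2) <= upper:
            return band
    return KAPPA_BANDS[-1][1]  # pragma: no cover


def interpret_v(v: float) -> str:
    if not 0.0 <= v <= 1.0 + 1e-12:
        raise ValueError(f"V out of range: {v}")
    for upper, band in V_BANDS:
        if v < upper:
            return band
    return V_BANDS[-1][1]
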