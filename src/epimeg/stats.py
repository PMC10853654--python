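"""Exact contingency-table inference for small surgical cohorts.

Fisher's exact test is implemented by direct hypergeometric enumeration
over the table support; the 2xK generalization (Freeman-Halton) enumerates
every table with the observed margins.  Point probabilities are computed
with exact integer binomial coefficients, so the two-sided criterion
("sum the probabilities of all tables no more probable than the observed
one") involves no floating-point tie ambiguity; a (1 + 1e-7) relative
slack is still applied for interface parity with mainstream packages.

Both sidedness conventions are first-class citizens: small surgical series
in the literature mix them freely, so every report in this package carries
one- and two-sided values side by side.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "ContingencyTable",
    "dichotomize_outcome",
    "build_table",
    "fisher_2x2",
    "freeman_halton_2xk",
    "chi_squared_2x2",
]

OUTCOME_COLUMNS = ("seizure_free", "not_seizure_free")

_TWO_SIDED_SLACK = 1.0 + 1e-7
_ENUMERATION_BUDGET = 10_000_000


@dataclass(frozen=True)
class ContingencyTable:
    """Rows x (seizure_free, not_seizure_free) counts with labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...] = OUTCOME_COLUMNS

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.ndim != 2 or (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be a nonnegative 2-d integer array")
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match the count matrix shape")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def row_proportions(self) -> np.ndarray:
        """Fraction of the first column (seizure-free) per row."""
        totals = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts[:, 0] / totals, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def dichotomize_outcome(engel_class: str, rule: str = "engel_I_vs_rest") -> str:
    """Map an Engel class (e.g. 'Ia', 'I', 'III') to the binary outcome.

    engel_I_vs_rest : seizure-free is Engel I (any subclass)
    engel_Ia_vs_rest: seizure-free is Engel Ia only; requires a subclass
                      on class-I entries.
    """
    s = engel_class.strip()
    roman = s.rstrip("abcd")
    sub = s[len(roman):]
    if roman not in ("I", "II", "III", "IV"):
        raise ValueError(f"unrecognized Engel class {engel_class!r}")
    if rule == "engel_I_vs_rest":
        return "seizure_free" if roman == "I" else "not_seizure_free"
    if rule == "engel_Ia_vs_rest":
        if roman == "I" and not sub:
            raise ValueError(
                "the Engel Ia rule needs subclasses on class-I entries"
            )
        return "seizure_free" if s == "Ia" else "not_seizure_free"
    raise ValueError(f"unknown dichotomization rule {rule!r}")


def build_table(
    df: pd.DataFrame,
    row_factor: str,
    row_order: Sequence[str],
    outcome_column: str = "outcome",
    subset: pd.Series | None = None,
) -> ContingencyTable:
    """Cross-tabulate a categorical column against the dichotomized outcome.

    ``df`` is a scored-cohort frame (one row per patient); ``subset`` is an
    optional boolean mask.  Rows appear in ``row_order``; missing levels
    get zero counts.  An empty subset is an error.
    """
    sub = df if subset is None else df[subset]
    if len(sub) == 0:
        raise ValueError("empty subset: no patients to tabulate")
    counts = np.zeros((len(row_order), len(OUTCOME_COLUMNS)), dtype=int)
    tab = pd.crosstab(sub[row_factor], sub[outcome_column])
    for i, r in enumerate(row_order):
        for j, c in enumerate(OUTCOME_COLUMNS):
            if r in tab.index and c in tab.columns:
                counts[i, j] = int(tab.loc[r, c])
    return ContingencyTable(counts=counts, row_labels=tuple(row_order))


# -- exact tests ------------------------------------------------------------

def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table.counts if isinstance(table, ContingencyTable) else table,
                   dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 integer table")
    return t


def fisher_2x2(table, sided: str = "two") -> float:
    """Fisher's exact test by hypergeometric enumeration.

    sided='one': smaller tail probability in the observed direction.
    sided='two': sum of point probabilities <= the observed one (with a
    tiny relative slack), the convention of mainstream packages.
    A table with a zero margin is degenerate and returns p = 1.
    """
    t = _as_2x2(table)
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1, c2 = int(t[:, 0].sum()), int(t[:, 1].sum())
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0

    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(n, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]

    if sided == "one":
        lower = sum(w for k, w in weights.items() if k <= a)
        upper = sum(w for k, w in weights.items() if k >= a)
        return min(min(lower, upper) / denom, 1.0)
    if sided == "two":
        cutoff = w_obs * _TWO_SIDED_SLACK
        total = sum(w for w in weights.values() if w <= cutoff)
        return min(total / denom, 1.0)
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def freeman_halton_2xk(table) -> float:
    """Exact 2xK test by full enumeration of tables with the observed
    margins (point-probability two-sided criterion).

    Reduces to the two-sided Fisher test at K = 2.  Raises when the margin
    space exceeds the enumeration budget.
    """
    t = np.asarray(table.counts if isinstance(table, ContingencyTable) else table,
                   dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2 or (t < 0).any():
        raise ValueError("need a nonnegative 2xK integer table, K >= 2")
    cols = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())
    if r1 == 0 or r1 == n or (cols == 0).any():
        return 1.0
    space = int(np.prod(cols + 1))
    if space > _ENUMERATION_BUDGET:
        raise ValueError(
            f"margin space of {space} tables exceeds the enumeration budget"
        )

    denom = comb(n, r1)
    w_obs = 1
    for cj, aj in zip(cols, t[0]):
        w_obs *= comb(int(cj), int(aj))

    k = len(cols)
    total = 0

    def recurse(j: int, remaining: int, weight: int) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= cols[j]:
                w = weight * comb(int(cols[j]), remaining)
                if w <= w_obs:  # exact integer comparison: no tie ambiguity
                    total += w
            return
        tail = int(cols[j + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(int(cols[j]), remaining)
        for aj in range(lo, hi + 1):
            recurse(j + 1, remaining - aj, weight * comb(int(cols[j]), aj))

    recurse(0, r1, 1)
    return min(total / denom, 1.0)


def chi_squared_2x2(table, correction: bool = True) -> float:
    """Pearson chi-squared p-value (optionally Yates-corrected); provided
    for completeness alongside the exact tests."""
    t = _as_2x2(table)
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return 1.0
    return float(chi2_contingency(t, correction=correction).pvalue)
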