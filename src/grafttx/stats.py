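"""Graft-success summaries and exact contingency-table tests.

Grafting experiments yield (trials, successes) counts per arm (scion/
stock combination or chemical treatment).  Arms are compared pairwise
with Fisher's exact test, computed by full enumeration of the
hypergeometric support of the fixed-margins table family; the two-sided
p-value follows the minimum-likelihood convention (sum of point
probabilities no larger than the observed one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import beta, hypergeom

from .enrichment import bh_adjust

_REL_SLACK = 1.0 + 1e-7  # relative tolerance when comparing point masses


@dataclass(frozen=True)
class GraftTrialRow:
    """One experimental arm: label, number of grafts attempted, number established."""

    label: str
    trials: int
    successes: int

    def __post_init__(self) -> None:
        if self.trials < 0 or self.successes < 0:
            raise ValueError("trials and successes must be >= 0")
        if self.successes > self.trials:
            raise ValueError(f"{self.label!r}: successes ({self.successes}) > trials ({self.trials})")

    @property
    def failures(self) -> int:
        return self.trials - self.successes


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    @classmethod
    def from_rows(cls, row1: GraftTrialRow, row2: GraftTrialRow) -> "ContingencyTable2x2":
        return cls(row1.successes, row1.failures, row2.successes, row2.failures)


@dataclass(frozen=True)
class SuccessRate:
    """Graft establishment rate in percent, exact and display-rounded."""

    exact: float
    rounded: int


def success_rate(row: GraftTrialRow) -> SuccessRate:
    """100 x successes/trials; rounded to the nearest integer percent,
    halves away from zero (so 27/28 prints as 96 and 27/35 as 77)."""
    if row.trials == 0:
        raise ValueError(f"{row.label!r}: success rate undefined for 0 trials")
    exact = 100.0 * row.successes / row.trials
    return SuccessRate(exact, int(math.floor(exact + 0.5)))


def fisher_exact_2x2(t: ContingencyTable2x2, alternative: str = "two_sided") -> float:
    """Exact p-value by enumeration of the fixed-margins support.

    With margins fixed, the top-left count X follows
    Hypergeometric(N, a+b, a+c); ``greater``/``less`` sum the upper/lower
    tail of X, ``two_sided`` sums every point probability <= the observed
    one (within a tiny relative slack against roundoff).  Any zero margin
    makes the table the only one in its family, hence p = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    N = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - N), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, r1, c1)
    p_obs = pmf[a - lo]
    if alternative == "two_sided":
        p = pmf[pmf <= p_obs * _REL_SLACK].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    # a sum covering the whole support is exactly 1 up to roundoff
    return 1.0 if p >= 1.0 - 1e-12 else float(p)


def pairwise_fisher(rows: list[GraftTrialRow]) -> "PairwiseFisherResult":
    """Two-sided Fisher tests for every unordered pair of arms.

    Returns symmetric raw and BH-adjusted p-value matrices (adjustment is
    over the family of all pairs; the diagonal is 1 by convention).
    """
    if len(rows) < 2:
        raise ValueError("pairwise_fisher needs >= 2 rows")
    for row in rows:
        if row.trials == 0:
            raise ValueError(f"{row.label!r}: cannot test an arm with 0 trials")
    labels = [r.label for r in rows]
    if len(set(labels)) != len(labels):
        raise ValueError("arm labels must be unique")
    pairs = list(combinations(range(len(rows)), 2))
    raw_vals = [
        fisher_exact_2x2(ContingencyTable2x2.from_rows(rows[i], rows[j])) for i, j in pairs
    ]
    adj_vals = bh_adjust(raw_vals)
    raw = pd.DataFrame(1.0, index=labels, columns=labels)
    adj = pd.DataFrame(1.0, index=labels, columns=labels)
    for (i, j), p, q in zip(pairs, raw_vals, adj_vals):
        raw.iloc[i, j] = raw.iloc[j, i] = p
        adj.iloc[i, j] = adj.iloc[j, i] = q
    return PairwiseFisherResult(raw=raw, adjusted=adj)


@dataclass
class PairwiseFisherResult:
    raw: pd.DataFrame
    adjusted: pd.DataFrame


def clopper_pearson(row: GraftTrialRow, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) confidence interval for the success rate, in percent."""
    k, n = row.successes, row.trials
    if n == 0:
        raise ValueError("interval undefined for 0 trials")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return 100.0 * lower, 100.0 * upper


def read_trials_tsv(path) -> list[GraftTrialRow]:
    """Read arm counts from a TSV with columns label, trials, successes."""
    t = pd.read_csv(path, sep="\t", dtype={"label": str})
    required = {"label", "trials", "successes"}
    if not required <= set(t.columns):
        raise ValueError(f"{path}: trials table needs columns {sorted(required)}")
    return [
        GraftTrialRow(str(r.label), int(r.trials), int(r.successes))
        for r in t.itertuples(index=False)
    ]


def trials_report(rows: list[GraftTrialRow]) -> pd.DataFrame:
    """Per-arm report: exact and rounded rates plus exact 95% CI."""
    recs = []
    for row in rows:
        rate = success_rate(row)
        lo, hi = clopper_pearson(row)
        recs.append(
            {
                "label": row.label,
                "trials": row.trials,
                "successes": row.successes,
                "rate_exact_pct": rate.exact,
                "rate_pct": rate.rounded,
                "ci95_low_pct": lo,
                "ci95_high_pct": hi,
            }
        )
    return pd.DataFrame(recs)
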