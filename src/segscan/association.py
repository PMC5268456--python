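"""Validation statistics: 2x2 knockout-lethality association and
Mann-Whitney rank comparison of SEG homologs against other genes.

The 2x2 analysis reports the cross-product odds ratio, a Woolf (logit)
95% confidence interval exp(ln OR +/- 1.96 * sqrt(1/Na + 1/Nb + 1/Nc +
1/Nd)), the two group proportions, and a two-tailed exact Fisher p-value
(point-probability convention). The rank comparison tests whether the
score ranks of a gene group (e.g. human homologs of rat SEGs, scored by
their own expression fold change or by a mutational-damage index) differ
from the remaining genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .enrichment import cross_product_odds_ratio

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "RankComparisonResult",
    "HomologMapReport",
    "two_by_two",
    "rank_compare",
    "map_homologs",
    "lethality_table",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

_ALTERNATIVES = {
    "two-sided": "two-sided",
    "group-lower": "less",
    "group-higher": "greater",
}

# exact Mann-Whitney enumeration is used below this product of group sizes
EXACT_LIMIT = 10_000


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows are group membership (e.g. SEG homolog vs other),
    columns are category membership (e.g. lethal knockout vs not).

    ``n_a``/``n_b`` are group members in / not in the category; ``n_c`` /
    ``n_d`` the same for the remaining genes.
    """

    n_a: int
    n_b: int
    n_c: int
    n_d: int

    def __post_init__(self) -> None:
        cells = (self.n_a, self.n_b, self.n_c, self.n_d)
        if any(int(c) != c or c < 0 for c in cells):
            raise ValueError("contingency cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    def swapped_rows(self) -> "ContingencyTable":
        return ContingencyTable(self.n_b, self.n_a, self.n_d, self.n_c)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    prop1: float
    prop2: float


def two_by_two(table: ContingencyTable) -> AssociationResult:
    """Odds ratio, Woolf 95% CI, proportions and exact two-tailed Fisher p
    for a 2x2 table.

    With any zero cell the OR falls back to its 0 / +inf sentinel and the
    CI is reported as NaN with a warning; the p-value is exact regardless.
    """
    a, b, c, d = table.n_a, table.n_b, table.n_c, table.n_d
    odds = cross_product_odds_ratio(a, b, c, d)
    if min(a, b, c, d) == 0:
        warnings.warn(
            "zero cell in 2x2 table: odds ratio is a sentinel and the Woolf "
            "confidence interval is undefined",
            stacklevel=2,
        )
        ci_low = ci_high = math.nan
    else:
        log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = math.exp(math.log(odds) - Z_95 * log_se)
        ci_high = math.exp(math.log(odds) + Z_95 * log_se)
    _, p = stats.fisher_exact([[a, c], [b, d]], alternative="two-sided")
    prop1 = a / (a + b) if a + b else math.nan
    prop2 = c / (c + d) if c + d else math.nan
    return AssociationResult(
        odds_ratio=odds,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=float(p),
        prop1=prop1,
        prop2=prop2,
    )


@dataclass(frozen=True)
class RankComparisonResult:
    n_group: int
    n_rest: int
    u_statistic: float
    p_value: float
    median_group: float
    median_rest: float
    alternative: str


def rank_compare(
    scores: Mapping[str, float],
    group: Iterable[str],
    alternative: str = "two-sided",
) -> RankComparisonResult:
    """Mann-Whitney U comparison of the score ranks of ``group`` against all
    remaining keys of ``scores``.

    Midranks are used for ties. The exact null distribution is enumerated
    when n_group * n_rest <= 10^4 and the scores are tie-free; otherwise
    the normal approximation with tie and continuity correction is used.
    ``alternative`` is ``two-sided``, ``group-lower`` or ``group-higher``
    (location of the group's scores relative to the rest).
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {sorted(_ALTERNATIVES)}; got {alternative!r}"
        )
    group_set = set(group)
    missing = group_set - scores.keys()
    if missing:
        raise ValueError(
            f"{len(missing)} group gene(s) have no score, e.g. {sorted(missing)[:3]}"
        )
    if not group_set:
        raise ValueError("group is empty")
    rest = [g for g in scores if g not in group_set]
    if not rest:
        raise ValueError("group covers every scored gene; nothing to compare against")
    x = np.array([scores[g] for g in sorted(group_set)], dtype=float)
    y = np.array([scores[g] for g in rest], dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=_ALTERNATIVES[alternative], method=method, use_continuity=True
    )
    return RankComparisonResult(
        n_group=int(x.size),
        n_rest=int(y.size),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_group=float(np.median(x)),
        median_rest=float(np.median(y)),
        alternative=alternative,
    )


@dataclass(frozen=True)
class HomologMapReport:
    mapped: frozenset[str]
    n_input: int
    n_unmapped: int


def map_homologs(
    genes: Iterable[str], mapping: Mapping[str, str]
) -> HomologMapReport:
    """Image of a gene set under a source-to-target homolog map; genes
    without a mapping are dropped and counted."""
    gene_list = set(genes)
    mapped = frozenset(mapping[g] for g in gene_list if g in mapping)
    n_unmapped = sum(1 for g in gene_list if g not in mapping)
    return HomologMapReport(mapped=mapped, n_input=len(gene_list), n_unmapped=n_unmapped)


def lethality_table(
    group: Iterable[str], phenotype: Mapping[str, bool]
) -> ContingencyTable:
    """Build the 2x2 table of group membership vs a binary phenotype over
    all phenotyped genes (e.g. SEG homologs vs lethal knockout)."""
    group_set = set(group) & phenotype.keys()
    n_a = sum(1 for g, lethal in phenotype.items() if lethal and g in group_set)
    n_b = len(group_set) - n_a
    n_lethal = sum(1 for lethal in phenotype.values() if lethal)
    n_c = n_lethal - n_a
    n_d = len(phenotype) - len(group_set) - n_c
    return ContingencyTable(n_a, n_b, n_c, n_d)
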