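"""Gene-set over-representation of SEGs by Fisher's exact test with
Benjamini-Hochberg FDR adjustment.

Each gene set is reduced to a 2x2 table over the analysis universe

                    in set   not in set
        SEG           Na        Nb
        non-SEG       Nc        Nd

with the cross-product odds ratio OR = (Na*Nd)/(Nb*Nc). The two-tailed
p-value is the exact point-probability Fisher test (sum of the
probabilities of all tables with the observed margins whose point
probability does not exceed that of the observed table). The universe is
the full post-preprocessing gene list, not the union of the gene sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix_io import GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "cross_product_odds_ratio",
    "bh_adjust",
    "enrich",
]


def cross_product_odds_ratio(n_a: int, n_b: int, n_c: int, n_d: int) -> float:
    """(Na*Nd)/(Nb*Nc) with sentinel values for zero cells: 0.0 when
    Na*Nd = 0, +inf when Nb*Nc = 0 (and Na*Nd > 0). No continuity
    correction is applied."""
    if n_a * n_d == 0:
        return 0.0
    if n_b * n_c == 0:
        return math.inf
    return (n_a * n_d) / (n_b * n_c)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned with the
    input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_seg_in: int
    n_seg_out: int
    n_other_in: int
    n_other_out: int
    odds_ratio: float
    p_value: float
    adjusted_p: float
    members_hit: tuple[str, ...]


def enrich(
    seg_genes: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
) -> list[EnrichmentResult]:
    """Fisher-exact over-representation of ``seg_genes`` in every set of
    ``collection``, BH-adjusted across the sets tested.

    Set members are intersected with the universe before counting; results
    are sorted by adjusted p (ties by raw p, then set name).
    """
    universe_set = set(universe)
    seg_set = set(seg_genes)
    if not universe_set:
        raise ValueError("universe is empty")
    stray = seg_set - universe_set
    if stray:
        raise ValueError(
            f"{len(stray)} SEG(s) not in universe, e.g. {sorted(stray)[:3]}"
        )
    n_seg = len(seg_set)
    n_other = len(universe_set) - n_seg

    rows: list[tuple[str, int, int, int, int, float, float, tuple[str, ...]]] = []
    for gene_set in collection:
        members = [g for g in gene_set.members if g in universe_set]
        hit = tuple(g for g in members if g in seg_set)
        n_a = len(hit)
        n_c = len(members) - n_a
        n_b = n_seg - n_a
        n_d = n_other - n_c
        odds = cross_product_odds_ratio(n_a, n_b, n_c, n_d)
        _, p = stats.fisher_exact([[n_a, n_c], [n_b, n_d]], alternative="two-sided")
        rows.append((gene_set.name, n_a, n_b, n_c, n_d, odds, float(p), hit))

    adjusted = bh_adjust([row[6] for row in rows])
    results = [
        EnrichmentResult(
            set_name=name,
            n_seg_in=n_a,
            n_seg_out=n_b,
            n_other_in=n_c,
            n_other_out=n_d,
            odds_ratio=odds,
            p_value=p,
            adjusted_p=float(adj),
            members_hit=hit,
        )
        for (name, n_a, n_b, n_c, n_d, odds, p, hit), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.set_name))
    return results
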