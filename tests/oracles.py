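"""Independent brute-force oracles used to check the package's statistics.

These deliberately avoid the code paths they verify: Fisher p-values are
summed from hypergeometric point probabilities over all tables with the
observed margins, BH adjustment is the textbook step-up written out by
hand, and small Mann-Whitney p-values are enumerated over all rank
assignments.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_pmf_exact(k: int, total: int, n_success: int, n_draw: int) -> Fraction:
    """Exact rational P(X = k) for a hypergeometric draw."""
    if k < 0 or k > n_draw or k > n_success or n_draw - k > total - n_success:
        return Fraction(0)
    return Fraction(
        math.comb(n_success, k) * math.comb(total - n_success, n_draw - k),
        math.comb(total, n_draw),
    )


def fisher_two_sided(n_a: int, n_b: int, n_c: int, n_d: int) -> float:
    """Two-tailed Fisher p by direct enumeration: the sum of point
    probabilities of every table with the observed margins whose point
    probability does not exceed the observed table's.

    Exact rational arithmetic makes the tie comparison unambiguous.
    """
    total = n_a + n_b + n_c + n_d
    row1 = n_a + n_c  # margin of the first category
    col1 = n_a + n_b  # margin of the first group
    p_obs = hypergeom_pmf_exact(n_a, total, row1, col1)
    p = Fraction(0)
    for k in range(max(0, col1 + row1 - total), min(row1, col1) + 1):
        pk = hypergeom_pmf_exact(k, total, row1, col1)
        if pk <= p_obs:
            p += pk
    return float(min(p, Fraction(1)))


def fisher_upper_tail(n_a: int, n_b: int, n_c: int, n_d: int) -> float:
    """One-sided (enrichment) hypergeometric tail P(X >= n_a)."""
    total = n_a + n_b + n_c + n_d
    row1 = n_a + n_c
    col1 = n_a + n_b
    p = sum(
        hypergeom_pmf_exact(k, total, row1, col1)
        for k in range(n_a, min(row1, col1) + 1)
    )
    return float(min(p, Fraction(1)))


def bh_step_up(p_values) -> list[float]:
    """Benjamini-Hochberg adjusted p-values, written out by hand."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def mannwhitney_exact_p(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p by enumerating every assignment of the pooled
    (tie-free) scores to the two groups. Only feasible for tiny samples."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free scores"
    n_x = len(x)

    def u_of(group):
        group_sorted = sorted(group)
        rank_sum = sum(pooled.index(v) + 1 for v in group_sorted)
        return rank_sum - n_x * (n_x + 1) / 2

    u_obs = u_of(x)
    n_total = 0
    n_le = n_ge = n_as_extreme = 0
    u_values = []
    for combo in itertools.combinations(pooled, n_x):
        u_values.append(u_of(combo))
    for u in u_values:
        n_total += 1
        if u <= u_obs:
            n_le += 1
        if u >= u_obs:
            n_ge += 1
    if alternative == "group-lower":
        return n_le / n_total
    if alternative == "group-higher":
        return n_ge / n_total
    # two-sided: double the smaller tail, capped at 1
    return min(1.0, 2 * min(n_le, n_ge) / n_total)
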