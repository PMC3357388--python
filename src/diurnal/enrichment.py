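"""Gene-set overrepresentation by the exact hypergeometric tail test.

One-sided enrichment of a query gene list against each set of a
collection, with the universe fixed to all genes on the expression
matrix, BH correction across sets, and Haldane-corrected odds ratios.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pandas as pd

from .errors import ValidationError
from .rhythms import bh_adjust


def hypergeometric_tail(k: int, set_size: int, list_size: int, universe: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe, set_size, list_size).

    Evaluated in exact integer arithmetic (sum of binomial products over
    the tail, divided once), so no cancellation can occur.
    """
    if not (0 <= set_size <= universe and 0 <= list_size <= universe):
        raise ValidationError(
            f"inconsistent counts: K={set_size}, n={list_size}, N={universe}"
        )
    if not 0 <= k <= min(set_size, list_size):
        raise ValidationError(
            f"overlap k={k} outside [0, min(K={set_size}, n={list_size})]"
        )
    numerator = sum(
        comb(set_size, j) * comb(universe - set_size, list_size - j)
        for j in range(k, min(set_size, list_size) + 1)
    )
    return float(Fraction(numerator, comb(universe, list_size)))


def enrich_gene_list(
    gene_list,
    universe,
    collection: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of ``gene_list`` in each set of ``collection``.

    Sets are intersected with the universe first; sets with no universe
    member are dropped. Returns one row per tested set with the overlap
    counts, Haldane-corrected odds ratio, exact p and BH q, sorted by p.
    """
    query = set(gene_list)
    background = set(universe)
    stray = query - background
    if stray:
        raise ValidationError(
            f"{len(stray)} query genes not in the universe, e.g. {sorted(stray)[:5]}"
        )
    n = len(query)
    big_n = len(background)
    rows = []
    for name, members in collection.items():
        in_universe = background.intersection(members)
        if not in_universe:
            continue
        big_k = len(in_universe)
        k = len(query & in_universe)
        p = hypergeometric_tail(k, big_k, n, big_n)
        a, b = k, n - k
        c, d = big_k - k, big_n - big_k - n + k
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b * c)
        rows.append((name, k, big_k, n, big_n, odds, p))
    table = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap_k",
            "set_size_K",
            "list_size_n",
            "universe_N",
            "odds_ratio",
            "p_value",
        ],
    )
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table["significant"] = table["q_value"] < alpha
        table = table.sort_values(["p_value", "set_name"], kind="stable").reset_index(
            drop=True
        )
    else:
        table["q_value"] = []
        table["significant"] = []
    return table
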