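"""Hypergeometric gene-category enrichment.

A query gene list (e.g. the CSF-induced pool) is tested against each
annotated category for over-representation relative to a gene universe
(the arrayed mouse genome), using the upper-tail hypergeometric
probability P(X >= k). Categories with zero overlap are not tested; BH
correction runs across the tested categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom

from .differential import adjust_bh

logger = logging.getLogger(__name__)


@dataclass
class CategoryAnnotation:
    """Category -> gene-set map over a fixed gene universe."""

    categories: dict[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("universe must be non-empty")
        self.categories = {c: frozenset(g) & self.universe for c, g in self.categories.items()}

    @classmethod
    def from_gmt(cls, path: str | Path, universe: Iterable[str] | None = None) -> "CategoryAnnotation":
        """Load GMT (name <tab> description <tab> gene...) annotations.

        If no universe is given, the union of all category genes is used.
        """
        categories: dict[str, frozenset] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                categories[fields[0]] = frozenset(g for g in fields[2:] if g)
        if universe is None:
            uni: frozenset = frozenset().union(*categories.values()) if categories else frozenset()
        else:
            uni = frozenset(universe)
        return cls(categories, uni)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Parameters: ``k`` observed overlap, ``K`` category size, ``n`` query
    size, ``N`` universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("need 0 <= K, n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("need 0 <= k <= min(K, n)")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_categories(
    query: Iterable[str],
    annot: CategoryAnnotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` in every overlapping category.

    Query genes outside the universe are dropped with a logged count.
    Returns one row per category with overlap k >= 1: ``category``, ``k``,
    ``K``, ``percent_of_query`` (100*k/|query|), ``p``, ``p_bh`` and a
    ``significant`` flag at ``alpha``, sorted by p.
    """
    q = frozenset(query)
    outside = q - annot.universe
    if outside:
        logger.info("dropping %d query genes outside the universe", len(outside))
    q &= annot.universe
    if not q:
        return pd.DataFrame(
            columns=["category", "k", "K", "percent_of_query", "p", "p_bh", "significant"]
        )
    N, n = len(annot.universe), len(q)
    rows = []
    for cat, genes in annot.categories.items():
        k = len(q & genes)
        if k == 0:
            continue
        rows.append(
            {
                "category": cat,
                "k": k,
                "K": len(genes),
                "percent_of_query": 100.0 * k / n,
                "p": hypergeometric_p(k, len(genes), n, N),
            }
        )
    table = pd.DataFrame(rows, columns=["category", "k", "K", "percent_of_query", "p"])
    if len(table):
        table["p_bh"] = adjust_bh(table["p"].to_numpy())
        table["significant"] = table["p_bh"] <= alpha
        table = table.sort_values(["p", "category"], kind="mergesort").reset_index(drop=True)
    else:
        table["p_bh"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
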