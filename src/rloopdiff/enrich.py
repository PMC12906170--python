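"""Gene-set over-representation (hypergeometric upper tail + BH) and Jaccard
similarity between enriched-term sets.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

__all__ = ["TermMap", "hypergeometric_enrichment", "enriched_terms", "jaccard_index"]

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """term_id -> gene set annotation against a fixed background universe."""

    terms: Mapping[str, frozenset[str]]
    background: frozenset[str]
    _: None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        self.background = frozenset(self.background)
        for term, genes in self.terms.items():
            if not genes <= self.background:
                raise ValueError(f"term {term!r} has genes outside the background")

    @classmethod
    def from_gmt(
        cls, terms: Mapping[str, Iterable[str]], background: Iterable[str] | None = None
    ) -> "TermMap":
        terms = {t: frozenset(g) for t, g in terms.items()}
        if background is None:
            background = frozenset().union(*terms.values()) if terms else frozenset()
        return cls(terms=terms, background=frozenset(background))


def hypergeometric_enrichment(query: Iterable[str], terms: TermMap) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    Query genes outside the background are dropped (count logged). For each
    term, p = P(X >= k) with k = |query ∩ term|, K = |term|, n = |query|,
    N = |background|; BH adjustment is applied within the tested term family.
    """
    query = set(query)
    outside = query - terms.background
    if outside:
        logger.info("dropping %d query genes outside the background", len(outside))
    query &= terms.background
    if not query:
        raise ValueError("empty query after intersecting with the background")
    n = len(query)
    n_bg = len(terms.background)
    rows = []
    for term, genes in terms.terms.items():
        k = len(query & genes)
        big_k = len(genes)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n))
        rows.append(
            {"term": term, "k": k, "K": big_k, "n": n, "N": n_bg, "p": min(p, 1.0)}
        )
    table = pd.DataFrame(rows).set_index("term")
    table["q"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table


def enriched_terms(table: pd.DataFrame, fdr_max: float = 0.05) -> frozenset[str]:
    """Terms significant at q < fdr_max."""
    return frozenset(table.index[table["q"] < fdr_max])


def jaccard_index(terms_a: Iterable, terms_b: Iterable) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(terms_a), set(terms_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
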