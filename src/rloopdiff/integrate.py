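"""Integration of differential R-loop regions with differential expression.

A gene's R-loop direction is "accumulated" if it hosts >= 1 validated
accumulated region (likewise "depleted"); a gene hosting both directions
contributes to both summaries, so region/gene counts are not additive across
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import DifferentialCalls

__all__ = [
    "ConcordanceSummary",
    "ResponseGroups",
    "RloopClassSummary",
    "overlap_regions_with_degs",
    "summarize_expression_by_rloop_class",
    "classify_response_groups",
    "venn_partition",
]


@dataclass(frozen=True)
class DirectionConcordance:
    n_regions: int
    de_up: int
    de_down: int
    not_de: int

    @property
    def n_de(self) -> int:
        return self.de_up + self.de_down

    @property
    def pct_up(self) -> float | None:
        """Percent DE-up among DE genes (pie denominator); None if no DE genes."""
        return 100.0 * self.de_up / self.n_de if self.n_de else None

    @property
    def pct_down(self) -> float | None:
        return 100.0 * self.de_down / self.n_de if self.n_de else None


@dataclass(frozen=True)
class ConcordanceSummary:
    """Cross-tabulation of R-loop host genes against DE status, per direction."""

    accumulated: DirectionConcordance
    depleted: DirectionConcordance


def _genes_by_direction(region_gene_table: pd.DataFrame) -> dict[str, set[str]]:
    t = region_gene_table[region_gene_table["gene_id"].astype(str) != ""]
    return {
        direction: set(t.loc[t["direction"] == direction, "gene_id"])
        for direction in ("up", "down")
    }


def overlap_regions_with_degs(
    region_gene_table: pd.DataFrame, de_calls: DifferentialCalls
) -> ConcordanceSummary:
    """Cross-tabulate genes hosting validated regions against DE calls.

    Percentages are computed among DE genes only, matching pie-chart
    denominators (e.g. 79 up + 7 down = 86 DE genes hosting accumulated
    regions -> 79/86 = 91.9% up).
    """
    genes = _genes_by_direction(region_gene_table)
    out = {}
    for direction, label in (("up", "accumulated"), ("down", "depleted")):
        hosts = genes[direction]
        n_regions = int((region_gene_table["direction"] == direction).sum())
        de_up = len(hosts & de_calls.up)
        de_down = len(hosts & de_calls.down)
        out[label] = DirectionConcordance(
            n_regions=n_regions,
            de_up=de_up,
            de_down=de_down,
            not_de=len(hosts) - de_up - de_down,
        )
    return ConcordanceSummary(accumulated=out["accumulated"], depleted=out["depleted"])


@dataclass(frozen=True)
class RloopClassSummary:
    """Expression log2FC distribution per R-loop class."""

    stats: pd.DataFrame  # rows: accumulated, depleted, unchanged
    members: dict[str, set[str]]


def summarize_expression_by_rloop_class(
    region_gene_table: pd.DataFrame, de_table: pd.DataFrame
) -> RloopClassSummary:
    """Group the transcriptome by R-loop class and summarize expression change.

    Classes: genes hosting >= 1 accumulated region, genes hosting >= 1 depleted
    region (a gene may appear in both), and all remaining tested genes
    ("unchanged"). Summaries are median and quartiles of expression log2FC.
    """
    genes = _genes_by_direction(region_gene_table)
    tested = set(de_table.index)
    members = {
        "accumulated": genes["up"] & tested,
        "depleted": genes["down"] & tested,
        "unchanged": tested - genes["up"] - genes["down"],
    }
    rows = []
    for label, gene_set in members.items():
        lfc = de_table.loc[sorted(gene_set), "log2fc"].to_numpy()
        if len(lfc):
            q1, med, q3 = np.percentile(lfc, [25, 50, 75])
        else:
            q1 = med = q3 = np.nan
        rows.append({"class": label, "n": len(lfc), "q1": q1, "median": med, "q3": q3})
    return RloopClassSummary(stats=pd.DataFrame(rows).set_index("class"), members=members)


@dataclass(frozen=True)
class ResponseGroups:
    """Six disjoint response groups from two genotypes' DE calls.

    Group I/II: changed only in genotype A (up/down); III/IV: shared up/down;
    V/VI: only in genotype B. Genes moving in opposite directions in the two
    genotypes are quarantined in ``discordant`` and belong to no group.
    """

    only_a_up: frozenset[str]
    only_a_down: frozenset[str]
    shared_up: frozenset[str]
    shared_down: frozenset[str]
    only_b_up: frozenset[str]
    only_b_down: frozenset[str]
    discordant: frozenset[str]

    @property
    def groups(self) -> dict[str, frozenset[str]]:
        return {
            "I": self.only_a_up,
            "II": self.only_a_down,
            "III": self.shared_up,
            "IV": self.shared_down,
            "V": self.only_b_up,
            "VI": self.only_b_down,
        }

    @property
    def total_a_up(self) -> int:
        return len(self.only_a_up) + len(self.shared_up)

    @property
    def total_a_down(self) -> int:
        return len(self.only_a_down) + len(self.shared_down)

    @property
    def total_b_up(self) -> int:
        return len(self.only_b_up) + len(self.shared_up)

    @property
    def total_b_down(self) -> int:
        return len(self.only_b_down) + len(self.shared_down)


def classify_response_groups(
    calls_a: DifferentialCalls, calls_b: DifferentialCalls
) -> ResponseGroups:
    """Partition DE genes by direction of change in each of two genotypes."""
    discordant = (calls_a.up & calls_b.down) | (calls_a.down & calls_b.up)
    return ResponseGroups(
        only_a_up=frozenset(calls_a.up - calls_b.up - discordant),
        only_a_down=frozenset(calls_a.down - calls_b.down - discordant),
        shared_up=frozenset(calls_a.up & calls_b.up),
        shared_down=frozenset(calls_a.down & calls_b.down),
        only_b_up=frozenset(calls_b.up - calls_a.up - discordant),
        only_b_down=frozenset(calls_b.down - calls_a.down - discordant),
        discordant=frozenset(discordant),
    )


def venn_partition(set_a: set, set_b: set) -> tuple[set, set, set]:
    """(A-only, shared, B-only) partition of two sets."""
    set_a, set_b = set(set_a), set(set_b)
    return set_a - set_b, set_a & set_b, set_b - set_a
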