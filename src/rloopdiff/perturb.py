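"""Perturbed-response analyses: RNase H1 sensitivity ("dampened" regions and
genes), cross-treatment three-tier consistency, and effect-size correlation
between two contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexp import CallParams, DifferentialCalls

__all__ = [
    "SensitivityClasses",
    "ConsistencyTiers",
    "classify_attenuation",
    "aggregate_gene_sensitivity",
    "cross_treatment_consistency",
    "effect_correlation",
]


def classify_attenuation(
    table_ref: pd.DataFrame,
    table_pert: pd.DataFrame,
    regions,
    assume_null: bool = False,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify regions as dampened under a perturbation.

    A region is *dampened* iff its perturbed-contrast log2FC is strictly
    smaller than its reference-contrast log2FC (``lfc_pert < lfc_ref``;
    equivalently ``delta = lfc_ref - lfc_pert > 0``). With ``assume_null``,
    regions missing from the perturbed table are scored as ``lfc_pert = 0``;
    otherwise a missing region is an error.

    Returns the per-region record table and summary counts/percentages.
    """
    regions = list(regions)
    records = []
    for region in regions:
        if region not in table_ref.index:
            raise KeyError(f"region {region!r} missing from reference table")
        if region in table_pert.index:
            lfc_pert = float(table_pert.at[region, "log2fc"])
        elif assume_null:
            lfc_pert = 0.0
        else:
            raise KeyError(f"region {region!r} missing from perturbed table")
        lfc_ref = float(table_ref.at[region, "log2fc"])
        delta = lfc_ref - lfc_pert
        records.append(
            {
                "region": region,
                "lfc_ref": lfc_ref,
                "lfc_pert": lfc_pert,
                "delta": delta,
                "class": "dampened" if lfc_pert < lfc_ref else "not_dampened",
            }
        )
    table = pd.DataFrame(
        records, columns=["region", "lfc_ref", "lfc_pert", "delta", "class"]
    )
    n = len(table)
    n_damp = int((table["class"] == "dampened").sum())
    summary = {
        "n": n,
        "dampened": n_damp,
        "not_dampened": n - n_damp,
        "pct_dampened": 100.0 * n_damp / n if n else float("nan"),
        "pct_not_dampened": 100.0 * (n - n_damp) / n if n else float("nan"),
    }
    return table, summary


@dataclass(frozen=True)
class SensitivityClasses:
    """Genes grouped by the RNase H1 response of the regions they host."""

    only_dampened: frozenset[str]
    only_increased: frozenset[str]
    both: frozenset[str]


def aggregate_gene_sensitivity(
    records: pd.DataFrame, region_gene_table: pd.DataFrame
) -> SensitivityClasses:
    """Aggregate region-level dampened/increased classes to host genes.

    A gene hosting both dampened and increased regions lands in ``both``;
    otherwise in the class of its regions.
    """
    gene_of = region_gene_table.set_index("region")["gene_id"].astype(str)
    damp: set[str] = set()
    incr: set[str] = set()
    for _, row in records.iterrows():
        gene = gene_of.get(row["region"], "")
        if not gene:
            continue
        (damp if row["class"] == "dampened" else incr).add(gene)
    return SensitivityClasses(
        only_dampened=frozenset(damp - incr),
        only_increased=frozenset(incr - damp),
        both=frozenset(damp & incr),
    )


@dataclass(frozen=True)
class ConsistencyTiers:
    """Per-direction fractions of reference-significant regions in treatment B:
    significant-consistent, nonsignificant-consistent, nonconsistent."""

    accumulation: dict[str, float]
    depletion: dict[str, float]
    counts: dict[str, dict[str, int]]


def _tier(lfc: float, q: float, sign: int, params: CallParams) -> str:
    if sign * lfc > params.lfc_min and q < params.fdr_max:
        return "significant_consistent"
    if sign * lfc > 0:
        return "nonsignificant_consistent"
    return "nonconsistent"


def cross_treatment_consistency(
    calls_ref: DifferentialCalls, table_b: pd.DataFrame, params: CallParams
) -> ConsistencyTiers:
    """Tier reference-significant regions by their behaviour in a second
    treatment.

    Accumulated reference regions: tier 1 if also significantly accumulated in
    B (log2FC > lfc_min and q < fdr_max), tier 2 if log2FC > 0 but not tier 1,
    tier 3 if log2FC <= 0. Depleted regions are mirrored (signs flipped).
    """
    tiers = ("significant_consistent", "nonsignificant_consistent", "nonconsistent")
    fractions: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for label, regions, sign in (
        ("accumulation", calls_ref.up, +1),
        ("depletion", calls_ref.down, -1),
    ):
        tally = {t: 0 for t in tiers}
        for region in regions:
            if region not in table_b.index:
                raise KeyError(f"region {region!r} missing from treatment-B table")
            tally[
                _tier(
                    float(table_b.at[region, "log2fc"]),
                    float(table_b.at[region, "q"]),
                    sign,
                    params,
                )
            ] += 1
        n = sum(tally.values())
        counts[label] = tally
        fractions[label] = {t: (tally[t] / n if n else float("nan")) for t in tiers}
    return ConsistencyTiers(
        accumulation=fractions["accumulation"],
        depletion=fractions["depletion"],
        counts=counts,
    )


def effect_correlation(
    table_1: pd.DataFrame, table_2: pd.DataFrame, regions
) -> tuple[float, float, int]:
    """Pearson correlation of two contrasts' log2FC over a region set.

    Returns (r, two-sided p from the t transform with n-2 df, n).
    """
    regions = [r for r in regions]
    missing = [r for r in regions if r not in table_1.index or r not in table_2.index]
    if missing:
        raise KeyError(f"regions missing from a table: {missing[:5]}")
    if len(regions) < 3:
        raise ValueError("need >= 3 common regions")
    x = table_1.loc[regions, "log2fc"].to_numpy()
    y = table_2.loc[regions, "log2fc"].to_numpy()
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(regions)
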