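"""DRIP-specific stages: fragment counting, the replicate count filter,
direction-aware peak validation, and annotation of validated regions.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import CountMatrix, DifferentialCalls
from .genome import (
    AnnotationIndex,
    BinGrid,
    Interval,
    annotate_interval,
    annotation_distribution,
    intersect_any,
    merge_intervals,
)

__all__ = [
    "PeakLibrary",
    "ValidatedCalls",
    "count_fragments_into_bins",
    "filter_bins",
    "validate_with_peaks",
    "annotate_calls",
    "INTRAGENIC_CATEGORIES",
]

# categories whose regions contribute to a direction's "annotated gene" list
INTRAGENIC_CATEGORIES = ("promoter", "gene_body", "tts_other")


def count_fragments_into_bins(
    fragments: Iterable[Interval], grid: BinGrid
) -> np.ndarray:
    """Count each fragment once, into the bin containing its midpoint."""
    column = np.zeros(len(grid), dtype=np.int64)
    for frag in fragments:
        grid.genome.require(frag)
        column[grid.index_at(frag.chrom, frag.midpoint)] += 1
    return column


def filter_bins(
    counts: CountMatrix, group_a: str, group_b: str, min_count: int = 20
) -> CountMatrix:
    """Keep bins with counts strictly above ``min_count`` in *every* replicate
    of at least one of the two groups."""
    for g in (group_a, group_b):
        if not counts.samples_in(g):
            raise ValueError(f"group {g!r} not in design")
    mat_a = counts.counts[counts.samples_in(group_a)].to_numpy()
    mat_b = counts.counts[counts.samples_in(group_b)].to_numpy()
    keep = (mat_a > min_count).all(axis=1) | (mat_b > min_count).all(axis=1)
    return counts.subset_features(counts.feature_ids[keep])


class PeakLibrary:
    """Merged peak intervals per (genotype, condition) group."""

    def __init__(self, merged: Mapping[tuple[str, str], Sequence[Interval]]):
        self._merged = {k: merge_intervals(v) for k, v in merged.items()}

    @classmethod
    def from_replicates(
        cls, replicates: Mapping[tuple[str, str], Sequence[Sequence[Interval]]]
    ) -> "PeakLibrary":
        """Merge the peaks of each condition's replicates into one set."""
        pooled = {
            key: [iv for rep in reps for iv in rep] for key, reps in replicates.items()
        }
        return cls(pooled)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._merged

    def __getitem__(self, key: tuple[str, str]) -> list[Interval]:
        if key not in self._merged:
            raise KeyError(f"no peak set for (genotype, condition) = {key}")
        return list(self._merged[key])

    def keys(self):
        return self._merged.keys()


@dataclass(frozen=True)
class ValidatedCalls:
    """Peak-validated ("bona fide") differential bins per direction."""

    up: tuple[Interval, ...]
    down: tuple[Interval, ...]
    contrast: str
    up_validated_by: tuple[str, str]
    down_validated_by: tuple[str, str]

    @property
    def up_set(self) -> frozenset[Interval]:
        return frozenset(self.up)

    @property
    def down_set(self) -> frozenset[Interval]:
        return frozenset(self.down)


def validate_with_peaks(
    calls: DifferentialCalls,
    peaks: PeakLibrary,
    up_condition_key: tuple[str, str],
    down_condition_key: tuple[str, str],
) -> ValidatedCalls:
    """Retain differential bins overlapping the peak set of the condition in
    which their signal is higher.

    Up (accumulated) bins must overlap the ``up_condition_key`` merged peaks
    by >= 1 bp; down (depleted) bins the ``down_condition_key`` peaks.
    """
    up_peaks = peaks[up_condition_key]
    down_peaks = peaks[down_condition_key]
    up_bins = sorted(Interval.from_name(f) for f in calls.up)
    down_bins = sorted(Interval.from_name(f) for f in calls.down)
    return ValidatedCalls(
        up=tuple(intersect_any(up_bins, up_peaks)),
        down=tuple(intersect_any(down_bins, down_peaks)),
        contrast=calls.contrast,
        up_validated_by=up_condition_key,
        down_validated_by=down_condition_key,
    )


def annotate_calls(
    validated: ValidatedCalls, index: AnnotationIndex
) -> tuple[pd.DataFrame, dict[str, dict[str, float]], dict[str, list[str]]]:
    """Annotate validated regions and summarize per direction.

    Returns the region-level annotation table (region, direction, category,
    gene_id, tss_distance), per-direction category fractions, and the
    deduplicated per-direction gene lists (regions annotated to a promoter,
    gene body, or TTS window).
    """
    rows = []
    fractions: dict[str, dict[str, float]] = {}
    gene_lists: dict[str, list[str]] = {}
    for direction, regions in (("up", validated.up), ("down", validated.down)):
        annotations = [annotate_interval(r, index) for r in regions]
        genes: list[str] = []
        for ann in annotations:
            rows.append(
                {
                    "region": ann.region.name(),
                    "direction": direction,
                    "category": ann.category,
                    "gene_id": ann.gene_id if ann.gene_id is not None else "",
                    "tss_distance": ann.tss_distance,
                }
            )
            if ann.category in INTRAGENIC_CATEGORIES and ann.gene_id not in genes:
                genes.append(ann.gene_id)
        gene_lists[direction] = genes
        if annotations:
            _, fractions[direction] = annotation_distribution(annotations)
        else:
            fractions[direction] = {}
    table = pd.DataFrame(
        rows, columns=["region", "direction", "category", "gene_id", "tss_distance"]
    )
    return table, fractions, gene_lists
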