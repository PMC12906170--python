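"""Genomic coordinate frame: intervals, fixed-width bins, and gene annotation.

All coordinates are 0-based half-open (BED convention). Two intervals overlap
iff they share a chromosome and ``max(starts) < min(ends)``; book-ended
intervals ([0,100) and [100,200)) therefore do *not* overlap, but they *are*
joined by :func:`merge_intervals` (bedtools-merge default distance 0).
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeDef",
    "Interval",
    "Bin",
    "BinGrid",
    "GeneModel",
    "AnnotationIndex",
    "RegionAnnotation",
    "make_bins",
    "intersect_any",
    "merge_intervals",
    "annotate_interval",
    "annotation_distribution",
    "metagene_profile",
    "CATEGORIES",
]

CATEGORIES = ("promoter", "gene_body", "tts_other", "intergenic")


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )

    def name(self) -> str:
        """Stable feature identifier, e.g. ``chr1:0-500``."""
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_name(cls, name: str) -> "Interval":
        chrom, _, span = name.rpartition(":")
        start, _, end = span.partition("-")
        return cls(chrom, int(start), int(end))


class GenomeDef:
    """Ordered chromosome-name -> length mapping defining the reference frame."""

    def __init__(self, chromosomes: Mapping[str, int]):
        chroms = dict(chromosomes)
        if len(chroms) != len(chromosomes):
            raise ValueError("duplicate chromosome names")
        for name, length in chroms.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chromosomes: dict[str, int] = chroms

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeDef) and self.chromosomes == other.chromosomes

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())

    def contains(self, iv: Interval) -> bool:
        return iv.chrom in self.chromosomes and iv.end <= self.chromosomes[iv.chrom]

    def require(self, iv: Interval) -> None:
        if not self.contains(iv):
            raise ValueError(f"interval {iv.name()} outside genome")


@dataclass(frozen=True)
class Bin:
    interval: Interval
    index: int


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    span: Interval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware)."""
        return self.span.end - 1 if self.strand == "+" else self.span.start


class BinGrid(Sequence[Bin]):
    """Fixed-width tiling of a genome; supports O(1) position -> bin lookup.

    Bins tile each chromosome without gaps or overlaps; every bin has the
    configured width except possibly the last bin of each chromosome. Bin
    indices are consecutive across chromosomes in genome order.
    """

    def __init__(self, genome: GenomeDef, width: int):
        if width < 1:
            raise ValueError("bin width must be >= 1")
        if len(genome) == 0:
            raise ValueError("no chromosomes")
        self.genome = genome
        self.width = width
        self._chrom_offset: dict[str, int] = {}
        bins: list[Bin] = []
        for chrom, length in genome.chromosomes.items():
            self._chrom_offset[chrom] = len(bins)
            for start in range(0, length, width):
                iv = Interval(chrom, start, min(start + width, length))
                bins.append(Bin(iv, len(bins)))
        self._bins = bins

    def __len__(self) -> int:
        return len(self._bins)

    def __getitem__(self, i):  # type: ignore[override]
        return self._bins[i]

    def __iter__(self) -> Iterator[Bin]:
        return iter(self._bins)

    def index_at(self, chrom: str, pos: int) -> int:
        """Index of the bin containing base ``pos``."""
        length = self.genome.chromosomes.get(chrom)
        if length is None or not (0 <= pos < length):
            raise ValueError(f"position {chrom}:{pos} outside genome")
        return self._chrom_offset[chrom] + pos // self.width

    def indices_overlapping(self, iv: Interval) -> range:
        """Indices of all bins overlapping ``iv`` (contiguous by construction)."""
        self.genome.require(iv)
        first = self.index_at(iv.chrom, iv.start)
        last = self.index_at(iv.chrom, iv.end - 1)
        return range(first, last + 1)

    def value_at(self, signal: Mapping[int, float], chrom: str, pos: int) -> float:
        """Signal of the bin under ``pos``; 0 outside the genome or for missing bins."""
        length = self.genome.chromosomes.get(chrom)
        if length is None or not (0 <= pos < length):
            return 0.0
        return float(signal.get(self.index_at(chrom, pos), 0.0))


def make_bins(genome: GenomeDef, width: int) -> BinGrid:
    """Tile ``genome`` into fixed-width bins (default analysis width 500 bp)."""
    return BinGrid(genome, width)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Minimal sorted non-overlapping set with identical base coverage.

    Abutting intervals are joined, matching ``bedtools merge`` at distance 0.
    """
    by_pos = sorted(intervals)
    merged: list[Interval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def intersect_any(
    queries: Iterable[Interval], subjects: Iterable[Interval]
) -> list[Interval]:
    """Queries overlapping >= 1 subject by >= 1 bp, reported whole (-wa semantics).

    Output preserves query order and identity; queries are never clipped.
    """
    merged = merge_intervals(subjects)
    starts: dict[str, list[int]] = {}
    ends: dict[str, list[int]] = {}
    for iv in merged:
        starts.setdefault(iv.chrom, []).append(iv.start)
        ends.setdefault(iv.chrom, []).append(iv.end)
    out: list[Interval] = []
    for q in queries:
        if q.chrom not in starts:
            continue
        # rightmost merged subject starting before q.end
        i = bisect.bisect_left(starts[q.chrom], q.end) - 1
        if i >= 0 and ends[q.chrom][i] > q.start:
            out.append(q)
    return out


@dataclass
class AnnotationIndex:
    """Gene models plus the window sizes defining annotation categories.

    The promoter window on the + strand is [TSS - promoter_up, TSS + promoter_down)
    and the TTS ("other") window is [TES - tts_up, TES + tts_down); both are
    mirrored on the - strand and clipped to chromosome bounds.
    """

    genes: Sequence[GeneModel]
    genome: GenomeDef
    promoter_up: int = 1000
    promoter_down: int = 100
    tts_up: int = 100
    tts_down: int = 1000
    _by_chrom: dict[str, list[GeneModel]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if min(self.promoter_up, self.promoter_down, self.tts_up, self.tts_down) < 0:
            raise ValueError("annotation window extents must be >= 0")
        seen: set[str] = set()
        self._by_chrom = {}
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            self.genome.require(g.span)
            self._by_chrom.setdefault(g.span.chrom, []).append(g)

    def _clip(self, chrom: str, lo: int, hi: int) -> tuple[int, int]:
        length = self.genome.chromosomes[chrom]
        return max(0, lo), min(length, hi)

    def promoter_window(self, gene: GeneModel) -> tuple[int, int]:
        if gene.strand == "+":
            lo, hi = gene.tss - self.promoter_up, gene.tss + self.promoter_down
        else:
            lo, hi = gene.tss - self.promoter_down + 1, gene.tss + self.promoter_up + 1
        return self._clip(gene.span.chrom, lo, hi)

    def tts_window(self, gene: GeneModel) -> tuple[int, int]:
        if gene.strand == "+":
            lo, hi = gene.tes - self.tts_up, gene.tes + self.tts_down
        else:
            lo, hi = gene.tes - self.tts_down + 1, gene.tes + self.tts_up + 1
        return self._clip(gene.span.chrom, lo, hi)


@dataclass(frozen=True)
class RegionAnnotation:
    region: Interval
    category: str
    gene_id: str | None
    tss_distance: int | None

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.category == "intergenic"):
            raise ValueError("gene_id must be None iff category is intergenic")


def _tss_distance(gene: GeneModel, pos: int) -> int:
    """Signed bp from gene TSS to ``pos``; positive = downstream of the TSS."""
    d = pos - gene.tss
    return d if gene.strand == "+" else -d


def annotate_interval(region: Interval, index: AnnotationIndex) -> RegionAnnotation:
    """Assign a single category at the region midpoint.

    Precedence: promoter > tts_other > gene_body > intergenic. Ties among
    genes within a category are broken by smallest |TSS distance|, then
    lexicographic gene_id, so annotation is fully deterministic.
    """
    index.genome.require(region)
    mid = region.midpoint
    candidates: dict[str, list[GeneModel]] = {c: [] for c in CATEGORIES[:3]}
    for gene in index._by_chrom.get(region.chrom, []):
        lo, hi = index.promoter_window(gene)
        if lo <= mid < hi:
            candidates["promoter"].append(gene)
        lo, hi = index.tts_window(gene)
        if lo <= mid < hi:
            candidates["tts_other"].append(gene)
        if gene.span.start <= mid < gene.span.end:
            candidates["gene_body"].append(gene)
    for category in ("promoter", "tts_other", "gene_body"):
        if candidates[category]:
            gene = min(
                candidates[category],
                key=lambda g: (abs(_tss_distance(g, mid)), g.gene_id),
            )
            return RegionAnnotation(region, category, gene.gene_id, _tss_distance(gene, mid))
    return RegionAnnotation(region, "intergenic", None, None)


def annotation_distribution(
    annotations: Iterable[RegionAnnotation],
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-category counts and fractions (fractions sum to 1)."""
    counts = {c: 0 for c in CATEGORIES}
    n = 0
    for ann in annotations:
        counts[ann.category] += 1
        n += 1
    if n == 0:
        raise ValueError("no regions")
    fractions = {c: counts[c] / n for c in CATEGORIES}
    return counts, fractions


def metagene_profile(
    signal: Mapping[int, float],
    grid: BinGrid,
    regions: Sequence[Interval],
    body_points: int = 50,
    flank_bp: int = 2000,
    flank_points: int = 20,
) -> np.ndarray:
    """Mean signal profile over regions rescaled to a common body length.

    Each region body is linearly resampled to ``body_points`` positions;
    flanks are sampled at fixed genomic resolution. Positions outside the
    genome, or bins missing from ``signal``, contribute 0. Returns a vector
    of length ``flank_points + body_points + flank_points``.
    """
    if body_points < 1:
        raise ValueError("body_points must be >= 1")
    if not regions:
        raise ValueError("no regions")
    total = np.zeros(2 * flank_points + body_points)
    for region in regions:
        vals = []
        for i in range(flank_points):
            pos = region.start - flank_bp + int((i + 0.5) * flank_bp / flank_points)
            vals.append(grid.value_at(signal, region.chrom, pos))
        for i in range(body_points):
            pos = region.start + int((i + 0.5) * region.width / body_points)
            vals.append(grid.value_at(signal, region.chrom, min(pos, region.end - 1)))
        for i in range(flank_points):
            pos = region.end + int((i + 0.5) * flank_bp / flank_points)
            vals.append(grid.value_at(signal, region.chrom, pos))
        total += np.asarray(vals)
    return total / len(regions)
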