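import numpy as np
import pytest

from rloopdiff.genome import (
    AnnotationIndex,
    GeneModel,
    GenomeDef,
    Interval,
    annotate_interval,
    annotation_distribution,
    intersect_any,
    make_bins,
    merge_intervals,
    metagene_profile,
)

from conftest import coverage_mask, random_intervals


class TestInterval:
    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (10, 2)])
    def test_rejects_degenerate_coordinates(self, start, end):
        with pytest.raises(ValueError):
            Interval("c1", start, end)

    def test_name_round_trip(self):
        iv = Interval("chr1", 1500, 2000)
        assert Interval.from_name(iv.name()) == iv


class TestMakeBins:
    @pytest.mark.parametrize(
        "lengths,width,expected",
        [
            ({"c1": 1250}, 500, [("c1", 0, 500), ("c1", 500, 1000), ("c1", 1000, 1250)]),
            ({"c1": 500}, 500, [("c1", 0, 500)]),
            (
                {"c1": 1000, "c2": 700},
                500,
                [("c1", 0, 500), ("c1", 500, 1000), ("c2", 0, 500), ("c2", 500, 700)],
            ),
        ],
    )
    def test_tiling_examples(self, lengths, width, expected):
        grid = make_bins(GenomeDef(lengths), width)
        got = [(b.interval.chrom, b.interval.start, b.interval.end) for b in grid]
        assert got == expected
        assert [b.index for b in grid] == list(range(len(expected)))

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="no chromosomes"):
            make_bins(GenomeDef({}), 500)

    def test_bins_partition_every_base(self):
        """Brute-force per-base check: each base covered by exactly one bin."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            genome = GenomeDef(
                {f"c{i}": int(rng.integers(1, 4000)) for i in range(int(rng.integers(1, 4)))}
            )
            width = int(rng.integers(1, 700))
            grid = make_bins(genome, width)
            cover = {c: np.zeros(ln, dtype=int) for c, ln in genome.chromosomes.items()}
            for b in grid:
                cover[b.interval.chrom][b.interval.start : b.interval.end] += 1
            assert all((v == 1).all() for v in cover.values())
            assert sum(b.interval.width for b in grid) == genome.total_length

    def test_position_lookup_matches_scan(self, grid):
        for b in grid:
            assert grid.index_at(b.interval.chrom, b.interval.start) == b.index
            assert grid.index_at(b.interval.chrom, b.interval.end - 1) == b.index


class TestIntersectAny:
    def test_one_bp_overlap_retained(self, small_genome):
        q = Interval("c1", 1000, 1500)
        assert intersect_any([q], [Interval("c1", 1499, 2000)]) == [q]

    def test_half_open_abutment_is_not_overlap(self):
        q = Interval("c1", 1000, 1500)
        assert intersect_any([q], [Interval("c1", 1500, 2000)]) == []

    def test_queries_reported_whole(self):
        q = Interval("c1", 1000, 1500)
        (hit,) = intersect_any([q], [Interval("c1", 1400, 2000)])
        assert hit == q  # -wa semantics: never clipped

    def test_matches_per_base_mask_oracle(self, small_genome):
        rng = np.random.default_rng(5)
        queries = random_intervals(rng, small_genome, 200)
        subjects = random_intervals(rng, small_genome, 200)
        masks = coverage_mask(subjects, small_genome)
        expected = [q for q in queries if masks[q.chrom][q.start : q.end].any()]
        assert intersect_any(queries, subjects) == expected


class TestMergeIntervals:
    def test_overlapping_merged(self):
        got = merge_intervals([Interval("c1", 0, 100), Interval("c1", 50, 150)])
        assert got == [Interval("c1", 0, 150)]

    def test_abutting_merged(self):
        got = merge_intervals([Interval("c1", 0, 100), Interval("c1", 100, 200)])
        assert got == [Interval("c1", 0, 200)]

    def test_mask_identical_and_count_minimal(self, small_genome):
        rng = np.random.default_rng(9)
        intervals = random_intervals(rng, small_genome, 500)
        merged = merge_intervals(intervals)
        for chrom, mask in coverage_mask(intervals, small_genome).items():
            got = coverage_mask([iv for iv in merged if iv.chrom == chrom], small_genome)[chrom]
            assert (got == mask).all()
            # minimal: number of merged intervals equals number of mask runs
            runs = int(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])).clip(min=0).sum())
            assert sum(iv.chrom == chrom for iv in merged) == runs


class TestAnnotateInterval:
    @pytest.fixture
    def index(self, small_genome):
        gene = GeneModel("g1", Interval("c1", 2000, 5000), "+")
        return AnnotationIndex([gene], small_genome, promoter_up=1000, promoter_down=100)

    def test_promoter_window(self, index):
        ann = annotate_interval(Interval("c1", 1400, 1900), index)  # midpoint 1650
        assert (ann.category, ann.gene_id) == ("promoter", "g1")

    def test_gene_body(self, index):
        ann = annotate_interval(Interval("c1", 3000, 3500), index)
        assert (ann.category, ann.gene_id) == ("gene_body", "g1")
        assert ann.tss_distance == 3250 - 2000

    def test_intergenic(self, index):
        ann = annotate_interval(Interval("c1", 8000, 8500), index)
        assert ann.category == "intergenic"
        assert ann.gene_id is None

    def test_outside_genome_rejected(self, index):
        with pytest.raises(ValueError, match="outside genome"):
            annotate_interval(Interval("c9", 0, 100), index)

    def test_minus_strand_promoter_is_mirrored(self, small_genome):
        gene = GeneModel("g2", Interval("c1", 2000, 5000), "-")  # TSS at 4999
        index = AnnotationIndex([gene], small_genome, promoter_up=1000, promoter_down=100)
        ann = annotate_interval(Interval("c1", 5200, 5700), index)  # midpoint 5450
        assert (ann.category, ann.gene_id) == ("promoter", "g2")
        assert ann.tss_distance == -(5450 - 4999)

    def test_nearest_tss_wins(self, small_genome):
        near = GeneModel("gz", Interval("c1", 3000, 4000), "+")  # TSS 3000, |d|=0
        far = GeneModel("ga", Interval("c1", 2000, 3000), "-")  # TSS 2999, |d|=1
        index = AnnotationIndex([near, far], small_genome, promoter_up=500, promoter_down=500)
        assert annotate_interval(Interval("c1", 2999, 3001), index).gene_id == "gz"

    def test_equal_distance_breaks_ties_lexicographically(self, small_genome):
        a = GeneModel("gb", Interval("c1", 3000, 4000), "+")  # TSS 3000
        b = GeneModel("ga", Interval("c1", 3000, 4500), "+")  # TSS 3000 as well
        index = AnnotationIndex([a, b], small_genome, promoter_up=500, promoter_down=500)
        region = Interval("c1", 2999, 3001)
        assert annotate_interval(region, index).gene_id == "ga"
        for _ in range(3):
            assert annotate_interval(region, index) == annotate_interval(region, index)


class TestAnnotationDistribution:
    def test_fraction_examples(self, small_genome):
        index = AnnotationIndex(
            [GeneModel("g1", Interval("c1", 2000, 5000), "+")], small_genome
        )
        regions = [Interval("c1", 3000 + i * 100, 3050 + i * 100) for i in range(3)]
        regions.append(Interval("c2", 6000, 6100))
        counts, fractions = annotation_distribution(
            annotate_interval(r, index) for r in regions
        )
        assert counts == {"promoter": 0, "gene_body": 3, "tts_other": 0, "intergenic": 1}
        assert fractions["gene_body"] == pytest.approx(0.75)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no regions"):
            annotation_distribution([])

    def test_matches_independent_tally(self, small_genome, three_genes):
        index = AnnotationIndex(three_genes, small_genome)
        rng = np.random.default_rng(17)
        anns = [
            annotate_interval(iv, index)
            for iv in random_intervals(rng, small_genome, 100)
        ]
        counts, fractions = annotation_distribution(anns)
        for cat in counts:
            expected = sum(1 for a in anns if a.category == cat)
            assert counts[cat] == expected
            assert fractions[cat] == pytest.approx(expected / len(anns))


class TestMetageneProfile:
    def test_uniform_signal_gives_constant_profile(self, grid):
        signal = {b.index: 2.5 for b in grid}
        prof = metagene_profile(signal, grid, [Interval("c1", 3000, 5000)], 10, 1000, 5)
        assert prof == pytest.approx(np.full(20, 2.5))

    def test_zero_flanks_when_signal_only_inside(self, grid):
        region = Interval("c1", 3000, 5000)
        signal = {i: 1.0 for i in grid.indices_overlapping(region)}
        prof = metagene_profile(signal, grid, [region], 10, 1000, 5)
        assert prof[:5] == pytest.approx(np.zeros(5))
        assert prof[-5:] == pytest.approx(np.zeros(5))
        assert prof[5:15] == pytest.approx(np.ones(10))

    def test_matches_naive_per_region_oracle(self, grid, small_genome):
        rng = np.random.default_rng(23)
        signal = {b.index: float(rng.random()) for b in grid}
        regions = random_intervals(rng, small_genome, 10, max_width=2000)
        body, fbp, fpts = 7, 900, 4
        prof = metagene_profile(signal, grid, regions, body, fbp, fpts)
        acc = np.zeros(body + 2 * fpts)
        for region in regions:
            row = []
            for i in range(fpts):
                row.append(grid.value_at(signal, region.chrom, region.start - fbp + int((i + 0.5) * fbp / fpts)))
            for i in range(body):
                pos = region.start + int((i + 0.5) * region.width / body)
                row.append(grid.value_at(signal, region.chrom, min(pos, region.end - 1)))
            for i in range(fpts):
                row.append(grid.value_at(signal, region.chrom, region.end + int((i + 0.5) * fbp / fpts)))
            acc += row
        assert prof == pytest.approx(acc / len(regions))

    def test_rejects_bad_body_points(self, grid):
        with pytest.raises(ValueError):
            metagene_profile({}, grid, [Interval("c1", 0, 100)], 0, 100, 2)
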