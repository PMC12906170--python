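import numpy as np
import pandas as pd
import pytest

from rloopdiff.genome import make_bins
from rloopdiff.regions import count_fragments_into_bins
from rloopdiff.simulate import (
    SimulationConfig,
    default_drip_design,
    simulate_bin_counts,
    simulate_expression_counts,
    simulate_fragments,
    simulate_peaks,
    simulate_truth,
    write_dataset,
)

SMALL = dict(
    chrom_lengths={"chr1": 200_000, "chr2": 200_000},
    n_genes=30,
    n_baseline_up=10,
    n_baseline_down=4,
    n_treatment_up=12,
    n_treatment_down=6,
    n_extra_de=5,
)


class TestSimulateTruth:
    def test_zero_attenuation_nullifies_mutant_treatment_effects(self):
        _, _, truth = simulate_truth(SimulationConfig(attenuation=0.0, seed=1, **SMALL))
        assert all(v == 0.0 for v in truth.regions["ir_at"].values())
        assert all(v == 0.0 for v in truth.de_genes["ir_at"].values())

    def test_unit_attenuation_copies_control_effects(self):
        _, _, truth = simulate_truth(SimulationConfig(attenuation=1.0, seed=1, **SMALL))
        assert truth.regions["ir_at"] == truth.regions["ir"]

    def test_suppression_scales_ir_effects(self):
        _, _, truth = simulate_truth(SimulationConfig(suppression=0.3, seed=1, **SMALL))
        for iv, lfc in truth.regions["ir"].items():
            assert truth.regions["rh_ir"][iv] == pytest.approx(0.3 * lfc)

    def test_full_coupling_links_every_host_gene(self):
        _, _, truth = simulate_truth(SimulationConfig(coupling_rho=1.0, seed=2, **SMALL))
        for contrast, source in (("genotype", "genotype"), ("ir", "ir")):
            for iv, lfc in truth.regions[source].items():
                host = truth.host_gene[iv]
                if host is None:
                    continue
                assert host in truth.de_genes[contrast]
                assert np.sign(truth.de_genes[contrast][host]) == np.sign(lfc)

    def test_regions_fall_on_bin_boundaries_and_do_not_overlap(self):
        config = SimulationConfig(seed=3, **SMALL)
        genome, _, truth = simulate_truth(config)
        grid = make_bins(genome, config.bin_width)
        seen = set()
        for by_iv in (truth.regions["genotype"], truth.regions["ir"]):
            for iv in by_iv:
                assert iv.start % config.bin_width == 0
                idx = set(grid.indices_overlapping(iv))
                assert not idx & seen
                seen |= idx

    def test_capacity_error(self):
        config = SimulationConfig(
            chrom_lengths={"chr1": 30_000}, n_genes=2, n_baseline_up=500,
            n_baseline_down=0, n_treatment_up=0, n_treatment_down=0, seed=1,
        )
        with pytest.raises(ValueError, match="capacity"):
            simulate_truth(config)


class TestBinCounts:
    def test_determinism(self):
        config = SimulationConfig(seed=5, **SMALL)
        genome, _, truth = simulate_truth(config)
        design = default_drip_design(config)
        a = simulate_bin_counts(genome, truth, design, config)
        b = simulate_bin_counts(genome, truth, design, config)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_poisson_mean_recovery_without_effects(self):
        config = SimulationConfig(
            chrom_lengths={"chr1": 5_000_000}, n_genes=10, n_baseline_up=0,
            n_baseline_down=0, n_treatment_up=0, n_treatment_down=0,
            n_extra_de=0, dispersion=0.0, libsize_range=(1.0, 1.0),
            baseline_mean=50.0, seed=6,
        )
        genome, _, truth = simulate_truth(config)
        design = {"a1": ("C", "UT"), "a2": ("C", "UT")}
        cm = simulate_bin_counts(genome, truth, design, config)
        n = len(cm.counts)
        assert n >= 10_000
        for col in cm.counts:
            assert cm.counts[col].mean() == pytest.approx(50.0, abs=3 * np.sqrt(50 / n))

    def test_injected_effect_reproduces_fold_change(self):
        config = SimulationConfig(
            seed=7, dispersion=0.01, libsize_range=(1.0, 1.0), n_reps=10, **SMALL
        )
        genome, _, truth = simulate_truth(config)
        grid = make_bins(genome, config.bin_width)
        design = default_drip_design(config)
        cm = simulate_bin_counts(genome, truth, design, config)
        ut = cm.counts[cm.samples_in("C.UT")].mean(axis=1)
        ir = cm.counts[cm.samples_in("C.IR")].mean(axis=1)
        lfc = truth.bin_lfc(grid, "ir")
        hot = np.flatnonzero(lfc != 0)
        est = np.log2(ir.iloc[hot].to_numpy() / ut.iloc[hot].to_numpy())
        assert est == pytest.approx(lfc[hot], abs=0.35)

    def test_attenuation_scales_empirical_effects(self):
        config = SimulationConfig(seed=8, attenuation=0.4, n_reps=6, **SMALL)
        genome, _, truth = simulate_truth(config)
        grid = make_bins(genome, config.bin_width)
        cm = simulate_bin_counts(genome, truth, default_drip_design(config), config)

        def mean_abs_lfc(geno):
            ut = cm.counts[cm.samples_in(f"{geno}.UT")].mean(axis=1)
            ir = cm.counts[cm.samples_in(f"{geno}.IR")].mean(axis=1)
            hot = np.flatnonzero(truth.bin_lfc(grid, "ir") != 0)
            return float(np.abs(np.log2(ir.iloc[hot].to_numpy() / ut.iloc[hot].to_numpy())).mean())

        ratio = mean_abs_lfc("AT") / mean_abs_lfc("C")
        assert ratio == pytest.approx(0.4, abs=0.12)


class TestExpressionCounts:
    def test_zero_effects_give_unit_group_ratio(self):
        config = SimulationConfig(
            seed=9, coupling_rho=0.0, libsize_range=(1.0, 1.0),
            **{**SMALL, "n_extra_de": 0},
        )
        genome, genes, truth = simulate_truth(config)
        design = {f"r{i}": ("C", "UT") if i < 3 else ("C", "IR") for i in range(6)}
        cm = simulate_expression_counts(genes, truth, design, config)
        ut = cm.counts[cm.samples_in("C.UT")].mean(axis=1)
        ir = cm.counts[cm.samples_in("C.IR")].mean(axis=1)
        assert float(np.median(ir / ut)) == pytest.approx(1.0, abs=0.1)

    def test_coupled_gene_fold_change(self):
        config = SimulationConfig(
            seed=10, coupling_rho=1.0, libsize_range=(1.0, 1.0), n_reps=10, **SMALL
        )
        genome, genes, truth = simulate_truth(config)
        design = {}
        for i in range(10):
            design[f"u{i}"] = ("C", "UT")
            design[f"t{i}"] = ("C", "IR")
        cm = simulate_expression_counts(genes, truth, design, config)
        ut = cm.counts[cm.samples_in("C.UT")].mean(axis=1)
        ir = cm.counts[cm.samples_in("C.IR")].mean(axis=1)
        for gene, lfc in truth.de_genes["ir"].items():
            est = np.log2(ir[gene] / ut[gene])
            assert est == pytest.approx(lfc, abs=0.5)

    def test_determinism(self):
        config = SimulationConfig(seed=11, **SMALL)
        genome, genes, truth = simulate_truth(config)
        design = {f"r{i}": ("C", "UT") if i < 3 else ("AT", "UT") for i in range(6)}
        a = simulate_expression_counts(genes, truth, design, config)
        b = simulate_expression_counts(genes, truth, design, config)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestPeaks:
    def test_perfect_peaks_equal_footprint(self):
        config = SimulationConfig(seed=12, peak_fn=0.0, peak_fp=0.0, **SMALL)
        _, _, truth = simulate_truth(config)
        peaks = simulate_peaks(truth, config)
        footprint = truth.footprint()
        for reps in peaks.values():
            for rep in reps:
                assert rep == footprint

    def test_total_false_negatives_empty_peaks(self):
        config = SimulationConfig(seed=13, peak_fn=1.0, peak_fp=0.0, **SMALL)
        _, _, truth = simulate_truth(config)
        peaks = simulate_peaks(truth, config)
        assert all(rep == [] for reps in peaks.values() for rep in reps)

    def test_decoys_bounded_and_disjoint_from_footprint(self):
        config = SimulationConfig(seed=14, peak_fn=0.0, peak_fp=0.1, **SMALL)
        _, _, truth = simulate_truth(config)
        footprint = set(truth.footprint())
        n_true = len(footprint)
        for reps in simulate_peaks(truth, config).values():
            for rep in reps:
                decoys = [iv for iv in rep if iv not in footprint]
                assert len(decoys) <= n_true  # Binomial(n_true, fp) upper bound
                for d in decoys:
                    assert not any(d.overlaps(t) for t in footprint)


class TestFragments:
    def test_zero_means_no_fragments(self, grid):
        config = SimulationConfig(seed=15)
        assert simulate_fragments({}, grid, config) == []

    @pytest.mark.parametrize("target_bin", [0, 5, 33])  # first, mid, last
    def test_midpoint_rule_inverts_counting_exactly(self, grid, target_bin):
        config = SimulationConfig(seed=16, fragment_length=300)
        fragments = simulate_fragments({target_bin: 40.0}, grid, config)
        assert fragments  # Poisson(40) > 0 a.s. at this seed
        column = count_fragments_into_bins(fragments, grid)
        assert column[target_bin] == len(fragments)
        assert column.sum() == len(fragments)

    def test_edge_fragments_stay_in_genome(self, grid):
        config = SimulationConfig(seed=17, fragment_length=300)
        means = {0: 50.0, len(grid) - 1: 50.0}
        for frag in simulate_fragments(means, grid, config):
            assert grid.genome.contains(frag)


class TestWriteDataset:
    def test_dataset_round_trip_and_determinism(self, tmp_path):
        config = SimulationConfig(seed=18, **SMALL)
        p1 = write_dataset(config, tmp_path / "d1")
        p2 = write_dataset(config, tmp_path / "d2")
        assert set(p1) == set(p2)
        for name in p1:
            with open(p1[name], "rb") as fa, open(p2[name], "rb") as fb:
                assert fa.read() == fb.read(), f"{name} not byte-identical"
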