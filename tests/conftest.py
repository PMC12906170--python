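import numpy as np
import pytest

from rloopdiff.genome import GenomeDef, GeneModel, Interval, make_bins
from rloopdiff.pipeline import RunConfig, run_pipeline
from rloopdiff.simulate import SimulationConfig, write_dataset


@pytest.fixture
def small_genome():
    return GenomeDef({"c1": 10_000, "c2": 7_000})


@pytest.fixture
def grid(small_genome):
    return make_bins(small_genome, 500)


@pytest.fixture
def three_genes(small_genome):
    return [
        GeneModel("g1", Interval("c1", 2000, 5000), "+"),
        GeneModel("g2", Interval("c1", 6000, 9000), "-"),
        GeneModel("g3", Interval("c2", 1000, 4000), "+"),
    ]


def random_intervals(rng, genome, n, max_width=800):
    """Random valid intervals over a genome."""
    chroms = list(genome.chromosomes.items())
    out = []
    for _ in range(n):
        chrom, length = chroms[int(rng.integers(len(chroms)))]
        width = int(rng.integers(1, max_width))
        start = int(rng.integers(0, max(1, length - width)))
        out.append(Interval(chrom, start, start + width))
    return out


def coverage_mask(intervals, genome):
    """Per-base boolean oracle for interval set operations."""
    masks = {c: np.zeros(ln, dtype=bool) for c, ln in genome.chromosomes.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


@pytest.fixture(scope="session")
def study_dataset(tmp_path_factory):
    """Default-condition synthetic study, written once per session."""
    outdir = tmp_path_factory.mktemp("dataset")
    config = SimulationConfig(seed=11)
    write_dataset(config, outdir)
    return config, outdir


@pytest.fixture(scope="session")
def study_run(study_dataset, tmp_path_factory):
    config, dataset = study_dataset
    outdir = tmp_path_factory.mktemp("results")
    run = run_pipeline(RunConfig(dataset=str(dataset), outdir=str(outdir), seed=11))
    return config, run
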