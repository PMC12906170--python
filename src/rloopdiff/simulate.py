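"""Seeded synthetic-data generator with known ground truth.

Emulates the statistical structure of a two-genotype (control "C" vs mutant
"AT"), four-condition (untreated "UT", irradiated "IR", peroxide "H2O2",
RNase-H1-overexpressing irradiated "RHIR") DRIP-Seq + RNA-Seq study:

* negative-binomial bin counts over a small genome with library-size
  variation and elevated baseline signal inside true R-loop regions;
* spike-in differential regions with |log2FC| drawn from a configured range;
* a genotype *attenuation* factor ``a`` scaling the mutant's treatment
  effects on the log scale, and a *suppression* factor ``sigma`` scaling
  treatment effects under RNase H1 overexpression;
* expression counts with a coupled gene subset (a true region's host gene is
  differentially expressed in the same direction with probability ``rho``);
* replicate peak sets covering the true R-loop footprint, with configurable
  false-negative dropouts and false-positive decoys.

Every random draw flows from the single config seed through labelled
substreams, so adding an output never perturbs the others and identical
config+seed gives byte-identical outputs.
"""

from __future__ import annotations

import os
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .diffexp import CountMatrix
from .genome import BinGrid, GeneModel, GenomeDef, Interval, make_bins, merge_intervals

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "GENOTYPES",
    "CONDITIONS",
    "simulate_truth",
    "simulate_bin_counts",
    "simulate_peaks",
    "simulate_expression_counts",
    "simulate_fragments",
    "simulate_term_map",
    "default_drip_design",
    "default_rna_design",
    "write_dataset",
]

GENOTYPES = ("C", "AT")
CONDITIONS = ("UT", "IR", "H2O2", "RHIR")

# contrast keys carried by the truth table
REGION_CONTRASTS = ("genotype", "ir", "ir_at", "h2o2", "h2o2_at", "rh_ir", "rh_ir_at")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome and counts."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_500_000, "chr2": 1_500_000}
    )
    bin_width: int = 500
    n_genes: int = 250
    gene_length_range: tuple[int, int] = (4_000, 12_000)
    n_reps: int = 3
    baseline_mean: float = 60.0
    enrichment: float = 4.0
    dispersion: float = 0.05
    libsize_range: tuple[float, float] = (0.7, 1.3)
    n_baseline_up: int = 80
    n_baseline_down: int = 30
    n_treatment_up: int = 120
    n_treatment_down: int = 60
    lfc_range: tuple[float, float] = (1.0, 3.0)
    region_bins_max: int = 3
    frac_intragenic: float = 0.7
    coupling_rho: float = 0.7
    attenuation: float = 0.4
    suppression: float = 0.3
    peak_fn: float = 0.05
    peak_fp: float = 0.05
    expression_baseline_mean: float = 200.0
    expression_dispersion: float = 0.05
    expression_lfc_range: tuple[float, float] = (1.0, 3.0)
    n_extra_de: int = 40
    fragment_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        rates = {
            "frac_intragenic": self.frac_intragenic,
            "coupling_rho": self.coupling_rho,
            "attenuation": self.attenuation,
            "suppression": self.suppression,
            "peak_fn": self.peak_fn,
            "peak_fp": self.peak_fp,
        }
        for name, value in rates.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.baseline_mean <= 0 or self.expression_baseline_mean <= 0:
            raise ValueError("baseline means must be > 0")
        if self.dispersion < 0 or self.expression_dispersion < 0:
            raise ValueError("dispersions must be >= 0")
        for lo, hi in (self.lfc_range, self.expression_lfc_range, self.libsize_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError("ranges must be finite with lo <= hi")

    def rng(self, label: str) -> np.random.Generator:
        """Labelled substream of the master seed."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])

    @property
    def genome(self) -> GenomeDef:
        return GenomeDef(self.chrom_lengths)


@dataclass
class TruthTable:
    """Ground truth: injected region and gene effects per contrast."""

    regions: dict[str, dict[Interval, float]]
    de_genes: dict[str, dict[str, float]]
    host_gene: dict[Interval, str | None]
    params: dict[str, float]

    def footprint(self) -> list[Interval]:
        """Merged union of all true R-loop region intervals."""
        all_regions = {iv for by_iv in self.regions.values() for iv in by_iv}
        return merge_intervals(all_regions)

    def bin_lfc(self, grid: BinGrid, contrast: str) -> np.ndarray:
        """Per-bin injected log2FC vector for one contrast."""
        out = np.zeros(len(grid))
        for iv, lfc in self.regions[contrast].items():
            out[list(grid.indices_overlapping(iv))] = lfc
        return out

    def true_bins(self, grid: BinGrid, contrast: str, direction: str) -> frozenset[str]:
        """Names of bins inside true regions of one direction."""
        sign = 1 if direction == "up" else -1
        names = set()
        for iv, lfc in self.regions[contrast].items():
            if sign * lfc > 0:
                for i in grid.indices_overlapping(iv):
                    names.add(grid[i].interval.name())
        return frozenset(names)


def _place_genes(config: SimulationConfig) -> list[GeneModel]:
    rng = config.rng("genes")
    genes: list[GeneModel] = []
    chroms = list(config.chrom_lengths.items())
    chrom_i = 0
    pos = {name: 2000 for name, _ in chroms}
    while len(genes) < config.n_genes:
        placed = False
        for _ in range(len(chroms)):
            name, length = chroms[chrom_i % len(chroms)]
            chrom_i += 1
            gene_len = int(rng.integers(*config.gene_length_range, endpoint=True))
            gap = int(rng.integers(1000, 3000))
            start = pos[name] + gap
            if start + gene_len + 2000 > length:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"g{len(genes):04d}", Interval(name, start, start + gene_len), strand)
            )
            pos[name] = start + gene_len
            placed = True
            break
        if not placed:
            raise ValueError("requested genes exceed genome capacity")
    return genes


def _sample_regions(
    config: SimulationConfig,
    grid: BinGrid,
    genes: Sequence[GeneModel],
    used_bins: set[int],
    n_up: int,
    n_down: int,
    rng: np.random.Generator,
) -> dict[Interval, tuple[float, str | None]]:
    """Bin-aligned non-overlapping true regions with injected effects."""
    gene_bin_ranges = []
    for g in genes:
        first = grid.index_at(g.span.chrom, g.span.start) + 1
        last = grid.index_at(g.span.chrom, g.span.end - 1) - 1
        if last - first >= config.region_bins_max:
            gene_bin_ranges.append((g, first, last))
    # bins well clear of any gene span (padded past promoter/TTS windows)
    genic = np.zeros(len(grid), dtype=bool)
    for g in genes:
        pad_lo = max(0, g.span.start - 2500)
        pad_hi = min(grid.genome.chromosomes[g.span.chrom], g.span.end + 2500)
        for i in grid.indices_overlapping(Interval(g.span.chrom, pad_lo, pad_hi)):
            genic[i] = True
    intergenic_bins = np.flatnonzero(~genic)

    out: dict[Interval, tuple[float, str | None]] = {}
    signs = [1.0] * n_up + [-1.0] * n_down
    host_sign: dict[str, float] = {}
    attempts = 0
    while signs:
        attempts += 1
        if attempts > 50 * (n_up + n_down):
            raise ValueError("requested regions exceed genome capacity")
        sign = signs[-1]
        width = int(rng.integers(1, config.region_bins_max, endpoint=True))
        if rng.random() < config.frac_intragenic and gene_bin_ranges:
            g, first, last = gene_bin_ranges[int(rng.integers(len(gene_bin_ranges)))]
            start_bin = int(rng.integers(first, last - width + 1, endpoint=True))
            host: str | None = g.gene_id
            # one effect direction per host gene within a contrast
            if host_sign.get(host, sign) != sign:
                continue
        else:
            start_bin = int(intergenic_bins[int(rng.integers(len(intergenic_bins)))])
            host = None
        bins = list(range(start_bin, start_bin + width))
        if bins[-1] >= len(grid):
            continue
        last_iv = grid[bins[-1]].interval
        first_iv = grid[bins[0]].interval
        if first_iv.chrom != last_iv.chrom or any(b in used_bins for b in bins):
            continue
        if host is None and any(genic[b] for b in bins):
            continue
        signs.pop()
        if host is not None:
            host_sign[host] = sign
        lfc = sign * rng.uniform(*config.lfc_range)
        used_bins.update(bins)
        out[Interval(first_iv.chrom, first_iv.start, last_iv.end)] = (lfc, host)
    return out


def simulate_truth(
    config: SimulationConfig,
) -> tuple[GenomeDef, list[GeneModel], TruthTable]:
    """Lay out the genome, genes, true differential regions, and coupled genes.

    Mutant-genotype treatment effects are the control effects scaled by
    ``attenuation`` on the log scale; RNase-H1 effects are the matching IR
    effects scaled by ``suppression``; the chemical (H2O2) contrast shares the
    IR truth and differs only by sampling noise.
    """
    genome = config.genome
    grid = make_bins(genome, config.bin_width)
    genes = _place_genes(config)
    rng = config.rng("regions")
    used: set[int] = set()
    baseline = _sample_regions(
        config, grid, genes, used, config.n_baseline_up, config.n_baseline_down, rng
    )
    treatment = _sample_regions(
        config, grid, genes, used, config.n_treatment_up, config.n_treatment_down, rng
    )
    a, sig = config.attenuation, config.suppression
    regions: dict[str, dict[Interval, float]] = {
        "genotype": {iv: lfc for iv, (lfc, _) in baseline.items()},
        "ir": {iv: lfc for iv, (lfc, _) in treatment.items()},
    }
    regions["ir_at"] = {iv: a * lfc for iv, lfc in regions["ir"].items()}
    regions["h2o2"] = dict(regions["ir"])
    regions["h2o2_at"] = dict(regions["ir_at"])
    regions["rh_ir"] = {iv: sig * lfc for iv, lfc in regions["ir"].items()}
    regions["rh_ir_at"] = {iv: sig * lfc for iv, lfc in regions["ir_at"].items()}

    host_gene = {iv: host for iv, (_, host) in {**baseline, **treatment}.items()}

    rng_de = config.rng("de_genes")
    de_genes: dict[str, dict[str, float]] = {k: {} for k in ("genotype", "ir")}
    for key, source in (("genotype", baseline), ("ir", treatment)):
        tried: set[str] = set()
        for iv, (lfc, host) in source.items():
            if host is None or host in tried:
                continue
            tried.add(host)
            if rng_de.random() < config.coupling_rho:
                de_genes[key][host] = float(
                    np.sign(lfc) * rng_de.uniform(*config.expression_lfc_range)
                )
        hosts = {h for _, h in source.values() if h is not None}
        free = [g.gene_id for g in genes if g.gene_id not in hosts]
        extra = rng_de.choice(len(free), size=min(config.n_extra_de, len(free)), replace=False)
        for j in extra:
            de_genes[key][free[int(j)]] = float(
                rng_de.choice([-1.0, 1.0]) * rng_de.uniform(*config.expression_lfc_range)
            )
    de_genes["ir_at"] = {g: a * lfc for g, lfc in de_genes["ir"].items()}
    de_genes["rh_ir"] = {g: sig * lfc for g, lfc in de_genes["ir"].items()}
    de_genes["rh_ir_at"] = {g: sig * lfc for g, lfc in de_genes["ir_at"].items()}

    truth = TruthTable(
        regions=regions,
        de_genes=de_genes,
        host_gene=host_gene,
        params={
            "attenuation": a,
            "suppression": sig,
            "coupling_rho": config.coupling_rho,
            "dispersion": config.dispersion,
        },
    )
    return genome, genes, truth


def _condition_delta(
    genotype: str, condition: str, lfc_of: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Injected log2 shift of one sample group relative to (C, UT)."""
    delta = np.zeros_like(lfc_of["genotype"])
    if genotype == "AT":
        delta = delta + lfc_of["genotype"]
    key = {"IR": "ir", "H2O2": "h2o2", "RHIR": "rh_ir"}.get(condition)
    if key is not None:
        delta = delta + lfc_of[key + ("_at" if genotype == "AT" else "")]
    return delta


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB with variance mu + dispersion * mu^2, via the gamma-Poisson mixture."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean * dispersion))


def default_drip_design(config: SimulationConfig) -> dict[str, tuple[str, str]]:
    """sample -> (genotype, condition) for the full DRIP-Seq design."""
    design = {}
    for g in GENOTYPES:
        for c in CONDITIONS:
            for r in range(1, config.n_reps + 1):
                design[f"{g}.{c}.rep{r}"] = (g, c)
    return design


def default_rna_design(config: SimulationConfig) -> dict[str, tuple[str, str]]:
    """RNA-Seq design: untreated and irradiated arms of both genotypes."""
    design = {}
    for g in GENOTYPES:
        for c in ("UT", "IR"):
            for r in range(1, config.n_reps + 1):
                design[f"rna.{g}.{c}.rep{r}"] = (g, c)
    return design


def _check_design(design: Mapping[str, tuple[str, str]]) -> None:
    per_group: dict[tuple[str, str], int] = {}
    for state in design.values():
        per_group[state] = per_group.get(state, 0) + 1
    bad = [g for g, n in per_group.items() if n < 2]
    if bad:
        raise ValueError(f"design needs >= 2 samples per group; short groups: {bad}")


def simulate_bin_counts(
    genome: GenomeDef,
    truth: TruthTable,
    design: Mapping[str, tuple[str, str]],
    config: SimulationConfig,
) -> CountMatrix:
    """NB bin counts: mean = s_j * lambda_i * 2^delta_ij.

    ``lambda_i`` is the baseline mean times the enrichment multiplier inside
    any true R-loop region; ``delta_ij`` is the injected log2FC applicable to
    sample j's (genotype, condition) state; ``s_j`` is a per-sample library
    factor drawn uniformly from the configured range.
    """
    _check_design(design)
    grid = make_bins(genome, config.bin_width)
    lam = np.full(len(grid), config.baseline_mean)
    for iv in truth.footprint():
        lam[list(grid.indices_overlapping(iv))] = config.baseline_mean * config.enrichment
    lfc_of = {k: truth.bin_lfc(grid, k) for k in REGION_CONTRASTS}
    samples = list(design)
    s = config.rng("drip_libsize").uniform(*config.libsize_range, size=len(samples))
    rng = config.rng("drip_counts")
    cols = {}
    for j, sample in enumerate(samples):
        delta = _condition_delta(*design[sample], lfc_of)
        mean = s[j] * lam * np.exp2(delta)
        cols[sample] = _nb_draw(rng, mean, config.dispersion)
    counts = pd.DataFrame(cols, index=[b.interval.name() for b in grid])
    groups = {sample: f"{g}.{c}" for sample, (g, c) in design.items()}
    return CountMatrix(counts, groups)


def simulate_expression_counts(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    design: Mapping[str, tuple[str, str]],
    config: SimulationConfig,
) -> CountMatrix:
    """NB gene counts with lognormal per-gene baselines and coupled effects."""
    _check_design(design)
    gene_ids = [g.gene_id for g in genes]
    base = config.rng("gene_baseline").lognormal(
        np.log(config.expression_baseline_mean), 0.5, size=len(gene_ids)
    )
    lfc_of = {}
    for key in ("genotype", "ir", "ir_at", "rh_ir", "rh_ir_at"):
        vec = np.zeros(len(gene_ids))
        table = truth.de_genes.get(key, {})
        for i, gid in enumerate(gene_ids):
            vec[i] = table.get(gid, 0.0)
        lfc_of[key] = vec
    # chemical damage shares the IR transcriptional truth
    lfc_of["h2o2"] = lfc_of["ir"]
    lfc_of["h2o2_at"] = lfc_of["ir_at"]
    samples = list(design)
    s = config.rng("expr_libsize").uniform(*config.libsize_range, size=len(samples))
    rng = config.rng("expr_counts")
    cols = {}
    for j, sample in enumerate(samples):
        delta = _condition_delta(*design[sample], lfc_of)
        mean = s[j] * base * np.exp2(delta)
        cols[sample] = _nb_draw(rng, mean, config.expression_dispersion)
    counts = pd.DataFrame(cols, index=gene_ids)
    groups = {sample: f"{g}.{c}" for sample, (g, c) in design.items()}
    return CountMatrix(counts, groups)


def simulate_peaks(
    truth: TruthTable,
    config: SimulationConfig,
    groups: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], list[list[Interval]]]:
    """Replicate peak sets per (genotype, condition).

    Each replicate's peaks are the true R-loop footprint intervals minus
    false-negative dropouts (probability ``peak_fn`` per interval) plus
    false-positive decoys (count ~ Binomial(n_true, peak_fp)) placed on bins
    outside the footprint.
    """
    if groups is None:
        groups = [(g, c) for g in GENOTYPES for c in CONDITIONS]
    footprint = truth.footprint()
    genome = config.genome
    grid = make_bins(genome, config.bin_width)
    covered = np.zeros(len(grid), dtype=bool)
    for iv in footprint:
        covered[list(grid.indices_overlapping(iv))] = True
    free_bins = np.flatnonzero(~covered)
    rng = config.rng("peaks")
    out: dict[tuple[str, str], list[list[Interval]]] = {}
    for key in groups:
        reps = []
        for _ in range(config.n_reps):
            kept = [iv for iv in footprint if rng.random() >= config.peak_fn]
            n_fp = int(rng.binomial(len(footprint), config.peak_fp))
            decoys = [
                grid[int(free_bins[i])].interval
                for i in rng.choice(len(free_bins), size=min(n_fp, len(free_bins)), replace=False)
            ]
            reps.append(sorted(kept + decoys))
        out[key] = reps
    return out


def simulate_fragments(
    bin_means: Mapping[int, float] | np.ndarray,
    grid: BinGrid,
    config: SimulationConfig,
    label: str = "fragments",
) -> list[Interval]:
    """Poisson fragments per bin with midpoints uniform inside the bin.

    Fragments have the configured length except near chromosome edges, where
    they are shrunk while preserving the midpoint, so counting them back into
    the generating bins under the midpoint rule reproduces the Poisson draws
    exactly.
    """
    rng = config.rng(label)
    means = np.zeros(len(grid))
    if isinstance(bin_means, Mapping):
        for i, m in bin_means.items():
            means[i] = m
    else:
        means[:] = np.asarray(bin_means)
    if (means < 0).any():
        raise ValueError("bin means must be >= 0")
    length = config.fragment_length
    fragments: list[Interval] = []
    for b in grid:
        n = int(rng.poisson(means[b.index]))
        if n == 0:
            continue
        chrom_len = grid.genome.chromosomes[b.interval.chrom]
        mids = rng.integers(b.interval.start, b.interval.end, size=n)
        for m in mids:
            m = int(m)
            a = min(length // 2, m)
            bb = min(length - length // 2, chrom_len - m)
            a = min(a, bb)  # keep midpoint: end-start asymmetry at most 1
            bb = min(bb, a + 1)
            fragments.append(Interval(b.interval.chrom, m - a, m + max(bb, 1)))
    return fragments


def simulate_term_map(
    genes: Sequence[GeneModel],
    truth: TruthTable,
    config: SimulationConfig,
    n_terms: int = 30,
    n_response_terms: int = 3,
) -> dict[str, frozenset[str]]:
    """Synthetic term -> gene annotation (GMT content).

    Mostly random draws from the gene universe, plus a few "response" terms
    drawn almost entirely from the coupled R-loop host genes (genotype and IR
    contrasts), so enrichment of the concordant gene sets is detectable.
    """
    rng = config.rng("terms")
    universe = [g.gene_id for g in genes]
    hosts = {h for h in truth.host_gene.values() if h is not None}

    def coupled_hosts(key: str) -> list[str]:
        return sorted(
            g for g, lfc in truth.de_genes.get(key, {}).items() if lfc > 0 and g in hosts
        )

    pools = {
        "BASE": coupled_hosts("genotype"),
        "IR": coupled_hosts("ir"),
        "SHARED": sorted(set(coupled_hosts("genotype")) | set(coupled_hosts("ir"))),
    }
    terms: dict[str, frozenset[str]] = {}
    for t in range(n_terms - 3 * n_response_terms):
        size = int(rng.integers(10, 30, endpoint=True))
        members = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        terms[f"SYNTH_GO_{t:04d}"] = frozenset(universe[int(i)] for i in members)
    for pool_name, pool in pools.items():
        for t in range(n_response_terms):
            size = int(rng.integers(15, 30, endpoint=True))
            n_resp = min(int(round(0.9 * size)), len(pool))
            picked = set(
                pool[int(i)] for i in rng.choice(len(pool), size=n_resp, replace=False)
            )
            filler = rng.choice(len(universe), size=size - len(picked), replace=False)
            picked.update(universe[int(i)] for i in filler)
            terms[f"SYNTH_GO_{pool_name}_{t:02d}"] = frozenset(picked)
    return terms


def write_dataset(config: SimulationConfig, outdir: str | os.PathLike) -> dict[str, str]:
    """Simulate the full study and write it as a plain-text dataset directory.

    Writes genome TSV, genes BED6, DRIP/RNA count + design TSVs, replicate
    peak BEDs, truth tables, a synthetic GMT, and a YAML echo of the config.
    Returns a manifest of the written paths.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    peaks_dir = os.path.join(outdir, "peaks")
    os.makedirs(peaks_dir, exist_ok=True)

    genome, genes, truth = simulate_truth(config)
    drip_design = default_drip_design(config)
    rna_design = default_rna_design(config)
    drip = simulate_bin_counts(genome, truth, drip_design, config)
    rna = simulate_expression_counts(genes, truth, rna_design, config)
    peaks = simulate_peaks(truth, config)
    terms = simulate_term_map(genes, truth, config)

    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    rio.write_genome_tsv(genome, _p("genome.tsv"))
    rio.write_genes_bed(genes, _p("genes.bed"))
    rio.write_counts_tsv(drip.counts, _p("drip_counts.tsv"))
    rio.write_counts_tsv(rna.counts, _p("rna_counts.tsv"))
    for name, design in (("drip_design.tsv", drip_design), ("rna_design.tsv", rna_design)):
        rows = [
            {"sample": s, "genotype": g, "condition": c, "replicate": s.rsplit("rep", 1)[-1]}
            for s, (g, c) in design.items()
        ]
        rio.write_design_tsv(pd.DataFrame(rows), _p(name))
    for (g, c), reps in peaks.items():
        for r, ivs in enumerate(reps, start=1):
            rel = os.path.join("peaks", f"{g}.{c}.rep{r}.bed")
            paths[rel] = os.path.join(outdir, rel)
            rio.write_bed(ivs, paths[rel])
    rio.write_gmt(terms, _p("terms.gmt"))

    region_rows = []
    for contrast, by_iv in truth.regions.items():
        for iv in sorted(by_iv):
            region_rows.append(
                {
                    "contrast": contrast,
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "log2fc": by_iv[iv],
                    "host_gene": truth.host_gene.get(iv) or "",
                }
            )
    pd.DataFrame(region_rows).to_csv(_p("truth_regions.tsv"), sep="\t", index=False)
    gene_rows = [
        {"contrast": contrast, "gene_id": gid, "log2fc": lfc}
        for contrast, by_gene in truth.de_genes.items()
        for gid, lfc in sorted(by_gene.items())
    ]
    pd.DataFrame(gene_rows).to_csv(_p("truth_genes.tsv"), sep="\t", index=False)
    with open(_p("config.yaml"), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return paths
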