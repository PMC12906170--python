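"""End-to-end orchestration: count -> filter -> test -> validate -> annotate
-> integrate -> perturb -> enrich, driven by a YAML run configuration.

The analysis plan is the study design itself: a genotype baseline contrast
(mutant vs control, untreated), within-genotype treatment contrasts (IR,
H2O2, RNase-H1+IR vs untreated), raw-p expression contrasts, and the
downstream classifications. Stages run only when their sample groups exist
in the design, so reduced datasets still run.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import io as rio
from .diffexp import CallParams, CountMatrix, DifferentialCalls, NegativeBinomialDiff
from .enrich import TermMap, enriched_terms, hypergeometric_enrichment, jaccard_index
from .genome import AnnotationIndex, Interval
from .integrate import (
    classify_response_groups,
    overlap_regions_with_degs,
    summarize_expression_by_rloop_class,
    venn_partition,
)
from .perturb import (
    aggregate_gene_sensitivity,
    classify_attenuation,
    cross_treatment_consistency,
    effect_correlation,
)
from .regions import PeakLibrary, annotate_calls, filter_bins, validate_with_peaks

__all__ = ["RunConfig", "PipelineRun", "ConfigError", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""


class StageError(Exception):
    """A pipeline stage failed; message names the stage."""


# (name, group A, group B, up-validation key, down-validation key)
DRIP_CONTRASTS = [
    ("baseline", "C.UT", "AT.UT", ("AT", "UT"), ("C", "UT")),
    ("ir_C", "C.UT", "C.IR", ("C", "IR"), ("C", "UT")),
    ("ir_AT", "AT.UT", "AT.IR", ("AT", "IR"), ("AT", "UT")),
    ("h2o2_C", "C.UT", "C.H2O2", ("C", "H2O2"), ("C", "UT")),
    ("rh_ir_C", "C.UT", "C.RHIR", ("C", "RHIR"), ("C", "UT")),
]
RNA_CONTRASTS = [
    ("rna_baseline", "C.UT", "AT.UT"),
    ("rna_ir_C", "C.UT", "C.IR"),
    ("rna_ir_AT", "AT.UT", "AT.IR"),
]


@dataclass
class RunConfig:
    """Paths and thresholds for one reproducible pipeline run."""

    dataset: str
    outdir: str
    bin_width: int = 500
    min_count: int = 20
    fdr_max: float = 0.05
    lfc_baseline: float = 1.0
    lfc_treatment: float = 1.5
    p_max_rna: float = 0.05
    enrichment_fdr: float = 0.05
    promoter_up: int = 1000
    promoter_down: int = 100
    tts_up: int = 100
    tts_down: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def path(self, name: str) -> str:
        return os.path.join(self.dataset, name)

    def validate(self) -> None:
        required = ["genome.tsv", "genes.bed", "drip_counts.tsv", "drip_design.tsv"]
        missing = [n for n in required if not os.path.exists(self.path(n))]
        if missing:
            raise ConfigError(f"dataset missing required files: {missing}")


@dataclass
class PipelineRun:
    """Artifacts and in-memory results of one pipeline execution."""

    config: RunConfig
    manifest: dict[str, int] = field(default_factory=dict)
    results: dict[str, Any] = field(default_factory=dict)

    def write(self, name: str, obj) -> str:
        path = os.path.join(self.config.outdir, name)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        if isinstance(obj, pd.DataFrame):
            keep_index = not isinstance(obj.index, pd.RangeIndex)
            obj.to_csv(
                path, sep="\t", index=keep_index, index_label="id" if keep_index else None
            )
            rows = len(obj)
        elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], Interval):
            rio.write_bed(obj, path)
            rows = len(obj)
        else:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
            rows = 1
        self.manifest[name] = rows
        return path


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Interval):
        return obj.name()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)


def _load_design(path: str) -> dict[str, str]:
    df = rio.read_design_tsv(path)
    return {r["sample"]: f"{r['genotype']}.{r['condition']}" for _, r in df.iterrows()}


def _load_peaks(dataset: str) -> PeakLibrary | None:
    pattern = os.path.join(dataset, "peaks", "*.bed")
    reps: dict[tuple[str, str], list[list[Interval]]] = {}
    for path in sorted(glob.glob(pattern)):
        stem = os.path.basename(path)[: -len(".bed")]
        genotype, condition, _rep = stem.split(".", 2)
        reps.setdefault((genotype, condition), []).append(rio.read_bed(path))
    if not reps:
        return None
    return PeakLibrary.from_replicates(reps)


def _groups_present(cm: CountMatrix, *groups: str) -> bool:
    return all(len(cm.samples_in(g)) >= 2 for g in groups)


def run_pipeline(config: RunConfig) -> PipelineRun:
    """Execute the full analysis plan; returns the run with its manifest.

    Deterministic given inputs: the differential engine and classifications
    contain no randomness, so identical datasets give byte-identical outputs.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    run = PipelineRun(config=config)
    stage = "load"
    try:
        genome = rio.read_genome_tsv(config.path("genome.tsv"))
        genes = rio.read_genes_bed(config.path("genes.bed"))
        index = AnnotationIndex(
            genes,
            genome,
            promoter_up=config.promoter_up,
            promoter_down=config.promoter_down,
            tts_up=config.tts_up,
            tts_down=config.tts_down,
        )
        drip = CountMatrix(
            rio.read_counts_tsv(config.path("drip_counts.tsv")),
            _load_design(config.path("drip_design.tsv")),
        )
        peaks = _load_peaks(config.dataset)

        stage = "drip_differential"
        drip_tables: dict[str, pd.DataFrame] = {}
        drip_calls: dict[str, DifferentialCalls] = {}
        region_gene: dict[str, pd.DataFrame] = {}
        gene_lists: dict[str, dict[str, list[str]]] = {}
        for name, a, b, up_key, down_key in DRIP_CONTRASTS:
            if not _groups_present(drip, a, b):
                continue
            lfc_min = config.lfc_baseline if name == "baseline" else config.lfc_treatment
            params = CallParams(fdr_max=config.fdr_max, lfc_min=lfc_min)
            kept = filter_bins(drip, a, b, min_count=config.min_count)
            result = NegativeBinomialDiff(kept).fit((a, b))
            drip_tables[name] = result.table
            calls = result.calls(params)
            drip_calls[name] = calls
            run.results[f"drip.{name}.table"] = result.table
            run.results[f"drip.{name}.calls"] = calls
            run.write(f"drip/{name}.table.tsv", result.table)
            logger.info("%s: %s", name, result.summary(params).replace("\n", " | "))
            if peaks is None or up_key not in peaks or down_key not in peaks:
                raise StageError(
                    f"drip_differential: missing peak set for {up_key} or {down_key}"
                )
            validated = validate_with_peaks(calls, peaks, up_key, down_key)
            table, fractions, by_dir = annotate_calls(validated, index)
            region_gene[name] = table
            gene_lists[name] = by_dir
            run.write(f"drip/{name}.validated_up.bed", list(validated.up))
            run.write(f"drip/{name}.validated_down.bed", list(validated.down))
            run.write(f"drip/{name}.annotation.tsv", table)
            run.write(f"drip/{name}.annotation_fractions.json", fractions)
            run.results[f"drip.{name}.validated"] = validated
            run.results[f"drip.{name}.fractions"] = fractions

        stage = "rna_differential"
        rna_tables: dict[str, pd.DataFrame] = {}
        rna_calls: dict[str, DifferentialCalls] = {}
        if os.path.exists(config.path("rna_counts.tsv")):
            rna = CountMatrix(
                rio.read_counts_tsv(config.path("rna_counts.tsv")),
                _load_design(config.path("rna_design.tsv")),
            )
            rna_params = CallParams(p_max=config.p_max_rna)
            for name, a, b in RNA_CONTRASTS:
                if not _groups_present(rna, a, b):
                    continue
                result = NegativeBinomialDiff(rna.subset_groups(a, b)).fit((a, b))
                rna_tables[name] = result.table
                rna_calls[name] = result.calls(rna_params)
                run.results[f"rna.{name}.table"] = result.table
                run.results[f"rna.{name}.calls"] = rna_calls[name]
                run.write(f"rna/{name}.table.tsv", result.table)

        stage = "integration"
        if "baseline" in region_gene and "rna_baseline" in rna_calls:
            concordance = overlap_regions_with_degs(
                region_gene["baseline"], rna_calls["rna_baseline"]
            )
            run.results["concordance.baseline"] = concordance
            run.write(
                "integration/concordance_baseline.json",
                {
                    d: vars(getattr(concordance, d))
                    for d in ("accumulated", "depleted")
                },
            )
            class_summary = summarize_expression_by_rloop_class(
                region_gene["baseline"], rna_tables["rna_baseline"]
            )
            run.results["class_summary.baseline"] = class_summary
            run.write("integration/expression_by_rloop_class.tsv", class_summary.stats)
        if "rna_ir_C" in rna_calls and "rna_ir_AT" in rna_calls:
            groups = classify_response_groups(rna_calls["rna_ir_C"], rna_calls["rna_ir_AT"])
            run.results["response_groups"] = groups
            run.write(
                "integration/response_groups.json",
                {**{k: v for k, v in groups.groups.items()}, "discordant": groups.discordant},
            )
        if "ir_C" in drip_calls and "ir_AT" in drip_calls:
            for direction in ("up", "down"):
                va = run.results["drip.ir_C.validated"]
                vb = run.results["drip.ir_AT.validated"]
                a_only, shared, b_only = venn_partition(
                    set(getattr(va, direction)), set(getattr(vb, direction))
                )
                run.results[f"venn.{direction}"] = (a_only, shared, b_only)
                run.write(
                    f"integration/venn_regions_{direction}.json",
                    {"C_only": a_only, "shared": shared, "AT_only": b_only},
                )
                g_only_a, g_shared, g_only_b = venn_partition(
                    set(gene_lists["ir_C"][direction]),
                    set(gene_lists["ir_AT"][direction]),
                )
                run.results[f"venn_genes.{direction}"] = (g_only_a, g_shared, g_only_b)
                run.write(
                    f"integration/venn_genes_{direction}.json",
                    {"C_only": g_only_a, "shared": g_shared, "AT_only": g_only_b},
                )

        stage = "perturbation"
        if "ir_C" in drip_tables and "rh_ir_C" in drip_tables:
            validated_up = [
                iv.name() for iv in run.results["drip.ir_C.validated"].up
            ]
            common = [
                r
                for r in validated_up
                if r in drip_tables["rh_ir_C"].index and r in drip_tables["ir_C"].index
            ]
            records, summary = classify_attenuation(
                drip_tables["ir_C"], drip_tables["rh_ir_C"], common
            )
            run.results["attenuation"] = (records, summary)
            run.write("perturbation/attenuation_records.tsv", records)
            run.write("perturbation/attenuation_summary.json", summary)
            sens = aggregate_gene_sensitivity(records, region_gene["ir_C"])
            run.results["sensitivity"] = sens
            run.write(
                "perturbation/gene_sensitivity.json",
                {
                    "only_dampened": sens.only_dampened,
                    "only_increased": sens.only_increased,
                    "both": sens.both,
                },
            )
        if "ir_C" in drip_calls and "h2o2_C" in drip_tables:
            tested = set(drip_tables["h2o2_C"].index)
            restricted = DifferentialCalls(
                up=drip_calls["ir_C"].up & tested,
                down=drip_calls["ir_C"].down & tested,
                params=drip_calls["ir_C"].params,
                contrast=drip_calls["ir_C"].contrast,
            )
            tiers = cross_treatment_consistency(
                restricted,
                drip_tables["h2o2_C"],
                CallParams(fdr_max=config.fdr_max, lfc_min=config.lfc_treatment),
            )
            run.results["consistency"] = tiers
            run.write(
                "perturbation/consistency_tiers.json",
                {"accumulation": tiers.accumulation, "depletion": tiers.depletion},
            )
            regions = sorted(
                (restricted.up | restricted.down) & set(drip_tables["ir_C"].index)
            )
            if len(regions) >= 3:
                r, p, n = effect_correlation(
                    drip_tables["ir_C"], drip_tables["h2o2_C"], regions
                )
                run.results["effect_correlation"] = (r, p, n)
                run.write(
                    "perturbation/effect_correlation.json", {"r": r, "p": p, "n": n}
                )

        stage = "enrichment"
        gmt_path = config.path("terms.gmt")
        if os.path.exists(gmt_path) and gene_lists:
            terms = TermMap.from_gmt(
                rio.read_gmt(gmt_path), background=[g.gene_id for g in genes]
            )
            enriched: dict[str, frozenset[str]] = {}
            for name, by_dir in gene_lists.items():
                for direction, members in by_dir.items():
                    if not members:
                        continue
                    label = f"{name}_{direction}"
                    table = hypergeometric_enrichment(members, terms)
                    run.write(f"enrichment/{label}.tsv", table)
                    enriched[label] = enriched_terms(table, config.enrichment_fdr)
            labels = sorted(enriched)
            jac = pd.DataFrame(
                [
                    [jaccard_index(enriched[a], enriched[b]) for b in labels]
                    for a in labels
                ],
                index=labels,
                columns=labels,
            )
            run.results["enriched_terms"] = enriched
            run.results["jaccard"] = jac
            run.write("enrichment/jaccard_matrix.tsv", jac)

        stage = "manifest"
        manifest_path = os.path.join(config.outdir, "manifest.json")
        with open(manifest_path, "w") as fh:
            json.dump(run.manifest, fh, indent=1, sort_keys=True)
    except (ConfigError, StageError):
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapper
        raise StageError(f"{stage}: {exc}") from exc
    return run
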