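"""Orchestration: screen -> gene test -> module search -> LD screen ->
enrichment, for one trait / sub-phenotype input set.

Every stage is a pure function of (inputs, config, seed); rerunning with the
same seed reproduces every output table byte for byte.  Empty intermediate
results (nothing passes a screen) propagate as empty outputs rather than
errors.  The run manifest records the configuration and the per-stage counts
(genes in the trait network, pruned variants, significant pairs, ...).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import (enrichment, epistasis_ld, gene_association, io_formats,
               network_modules, selection_screen)
from .io_formats import (GeneAnnotation, GeneSetCollection, GenotypePanel,
                         VariantRecord)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage-level failure; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    # input paths (unused when in-memory inputs are supplied)
    summary_stats: str | None = None
    vcf: str | None = None
    ihs_table: str | None = None
    gene_bed: str | None = None
    ppi_edges: str | None = None
    gmt: str | None = None
    # selection screen
    ihs_threshold: float = 1.5
    ihs_match_by: str = "id"          # or "position"
    compute_ihs: bool = False         # derive iHS from phased VCF haplotypes
    # gene-based test
    flank_bp: int = 0
    gene_n_sims: int = 1_000
    gene_max_sims: int = 1_000_000
    gene_adaptive: bool = True
    # module search
    module_r: float = 0.1
    n_top: int = 10
    module_n_perm: int = 100_000
    module_d: int = 1
    # epistasis screen
    r2_prune: float = 0.8
    long_range_bp: int = 10_000_000
    nominal_alpha: float = 0.05
    ld_n_perm: int = 10_000
    q_threshold: float = 0.05
    # enrichment
    min_overlap: int = 2
    # randomness
    seed: int = 0
    analysis_label: str = "trait"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError("config", "unknown_keys",
                                f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineInputs:
    summary_stats: list[VariantRecord]
    panel: GenotypePanel
    annotation: list[GeneAnnotation]
    ppi: nx.Graph
    gmt: GeneSetCollection
    ihs_table: pd.DataFrame | None = None   # precomputed standardized iHS


@dataclass
class PipelineResult:
    config: PipelineConfig
    screened: list[VariantRecord]
    gene_scores: list[gene_association.GeneScore]
    modules: list[network_modules.Module]
    network_genes: set[str]
    pruned: list[VariantRecord]
    pair_table: pd.DataFrame
    sig_pairs: pd.DataFrame
    gene_set_graph: nx.MultiGraph
    enrichment_results: list[enrichment.EnrichmentResult]
    manifest: dict = field(default_factory=dict)


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    required = {"summary_stats": config.summary_stats, "vcf": config.vcf,
                "gene_bed": config.gene_bed, "ppi_edges": config.ppi_edges,
                "gmt": config.gmt}
    missing = [k for k, v in required.items() if not v]
    if missing:
        raise PipelineError("io", "missing_inputs",
                            f"missing input paths: {missing}")
    ihs = None
    if config.ihs_table:
        ihs = io_formats.read_ihs_table(config.ihs_table)
    elif not config.compute_ihs:
        raise PipelineError("io", "missing_inputs",
                            "need either an iHS table or compute_ihs=true")
    return PipelineInputs(
        summary_stats=io_formats.read_summary_stats(config.summary_stats),
        panel=io_formats.read_genotypes_vcf(config.vcf),
        annotation=io_formats.read_gene_bed(config.gene_bed),
        ppi=io_formats.read_ppi_edges(config.ppi_edges),
        gmt=io_formats.read_gmt(config.gmt),
        ihs_table=ihs,
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ["gene_test", "modules", "ld"]
    states = ss.generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, states)}


def run_pipeline(config: PipelineConfig,
                 inputs: PipelineInputs | None = None) -> PipelineResult:
    """Execute the five analysis stages for one trait input set."""
    if inputs is None:
        inputs = load_inputs(config)
    seeds = _stage_seeds(config.seed)

    # --- stage 1: selection screen -------------------------------------
    ihs_table = inputs.ihs_table
    if ihs_table is None:
        if inputs.panel.haplotypes is None:
            raise PipelineError("selection_screen", "unphased_panel",
                                "iHS computation needs phased haplotypes")
        ihs_table = selection_screen.ihs_scores(inputs.panel)
    variants = selection_screen.attach_ihs(inputs.summary_stats, ihs_table,
                                           match_by=config.ihs_match_by)
    screened = selection_screen.filter_by_ihs(variants,
                                              threshold=config.ihs_threshold)

    # --- stage 2: gene-based association --------------------------------
    gene_map = gene_association.map_snps_to_genes(screened, inputs.annotation,
                                                  flank_bp=config.flank_bp)
    scores = gene_association.score_genes(
        gene_map, inputs.panel, n_sims=config.gene_n_sims,
        seed=seeds["gene_test"], adaptive=config.gene_adaptive,
        max_sims=config.gene_max_sims)

    # --- stage 3: dense-module search ------------------------------------
    on_network = [s for s in scores if s.gene_id in inputs.ppi]
    if on_network:
        modules, network_genes = network_modules.search_and_select(
            inputs.ppi, scores, r=config.module_r, n_top=config.n_top,
            n_perm=config.module_n_perm, seed=seeds["modules"],
            d=config.module_d)
    else:
        logger.warning("no scored genes on the PPI network; downstream "
                       "stages will be empty")
        modules, network_genes = [], set()

    # --- stage 4: long-distance genotypic-LD screen ----------------------
    network_variants = [v for g in sorted(network_genes)
                        for v in gene_map.get(g, ())]
    # a variant may sit in several network genes; dedupe by id
    network_variants = list({v.variant_id: v for v in network_variants}.values())
    variant_genes = {
        v.variant_id: {g for g in network_genes
                       if v in gene_map.get(g, ())}
        for v in network_variants}
    pruned = epistasis_ld.prune_r2(network_variants, inputs.panel,
                                   r2_threshold=config.r2_prune)
    pairs = epistasis_ld.candidate_pairs(pruned, variant_genes,
                                         nominal_alpha=config.nominal_alpha,
                                         long_range_bp=config.long_range_bp)
    pair_table = epistasis_ld.test_pairs(inputs.panel, pairs,
                                         n_perm=config.ld_n_perm,
                                         seed=seeds["ld"])
    sig = epistasis_ld.significant_pairs(pair_table,
                                         q_threshold=config.q_threshold)

    # --- stage 5: gene set and enrichment --------------------------------
    gene_p = {s.gene_id: s.p_gene for s in scores}
    graph = epistasis_ld.build_adaptation_gene_set(
        sig, variant_genes, inputs.ppi, gene_p=gene_p,
        analysis_label=config.analysis_label)
    study = set(graph.nodes())
    background = ({g.gene_id for g in inputs.annotation}
                  & set(inputs.gmt.universe))
    if study and background:
        enr = enrichment.enrich_gene_set(study & background, inputs.gmt,
                                         background,
                                         min_overlap=config.min_overlap) \
            if study & background else []
    else:
        enr = []

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "counts": {
            "input_variants": len(inputs.summary_stats),
            "screened_variants": len(screened),
            "scored_genes": len(scores),
            "modules_returned": len(modules),
            "network_genes": len(network_genes),
            "network_variants": len(network_variants),
            "pruned_variants": len(pruned),
            "candidate_pairs": len(pairs),
            "significant_pairs": len(sig),
            "gene_set_genes": len(study),
            "terms_tested": len(enr),
        },
    }
    return PipelineResult(config=config, screened=screened, gene_scores=scores,
                          modules=modules, network_genes=network_genes,
                          pruned=pruned, pair_table=pair_table, sig_pairs=sig,
                          gene_set_graph=graph, enrichment_results=enr,
                          manifest=manifest)


def write_results(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write per-stage tables, the gene-set graph, and the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    screened_df = pd.DataFrame(
        [(v.variant_id, v.chrom, v.pos, v.p_gwas, v.ihs)
         for v in result.screened],
        columns=["variant_id", "chrom", "pos", "p_gwas", "ihs"])
    paths["screened"] = out / "screened_variants.tsv"
    io_formats.write_table(screened_df, paths["screened"])

    paths["gene_scores"] = out / "gene_scores.tsv"
    io_formats.write_table(
        gene_association.gene_scores_table(result.gene_scores),
        paths["gene_scores"])

    paths["modules"] = out / "modules.tsv"
    io_formats.write_table(network_modules.modules_table(result.modules),
                           paths["modules"])

    pruned_df = pd.DataFrame(
        [(v.variant_id, v.chrom, v.pos, v.p_gwas) for v in result.pruned],
        columns=["variant_id", "chrom", "pos", "p_gwas"])
    paths["pruned"] = out / "pruned_variants.tsv"
    io_formats.write_table(pruned_df, paths["pruned"])

    paths["pairs"] = out / "ld_pairs.tsv"
    io_formats.write_table(result.pair_table, paths["pairs"])
    paths["significant"] = out / "significant_pairs.tsv"
    io_formats.write_table(result.sig_pairs, paths["significant"])

    paths["gene_set"] = out / "gene_set_edges.tsv"
    io_formats.write_table(
        epistasis_ld.gene_set_edges_table(result.gene_set_graph),
        paths["gene_set"])

    paths["enrichment"] = out / "enrichment.tsv"
    io_formats.write_table(
        enrichment.enrichment_table(result.enrichment_results),
        paths["enrichment"])

    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    paths["config"] = out / "config.yaml"
    paths["config"].write_text(yaml.safe_dump(result.config.to_dict(),
                                              sort_keys=True))
    return paths
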