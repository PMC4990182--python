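"""Synthetic input bundles with planted signal at every pipeline stage.

The generator emulates the statistical structure the analysis assumes, so
the full pipeline can be exercised and parameter-recovery can be measured
without any external resources:

* a phased haplotype panel with partial selective sweeps (founder-copy
  model) so |iHS| is genuinely elevated at planted core variants;
* GWAS summary statistics that are null-uniform except in planted trait
  genes, whose SNPs draw two-sided p-values from z ~ Normal(mu_alt, 1);
* a scale-free (preferential-attachment) protein-interaction network with
  a planted module additionally wired as Erdos-Renyi(q_in);
* planted cross-chromosome genotype dependence (epistasis): one variant's
  dosages copy another's with probability 1 - epsilon;
* GMT gene sets containing one "true" term (the planted genes) among
  random background terms.

Everything is driven by a single seeded NumPy generator, so a given
configuration is bit-reproducible.  The sweep is a founder-copy
approximation, not a coalescent simulation: carrier haplotypes copy a
founder template outward from the core until an Exponential(rho)
breakpoint, with per-site copy errors at rate mu.  Genotypes are in
Hardy-Weinberg proportions by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .io_formats import (GeneAnnotation, GeneSetCollection, GenotypePanel,
                         VariantRecord, write_gene_bed, write_genotypes_vcf,
                         write_gmt, write_ihs_table, write_ppi_edges,
                         write_summary_stats)

logger = logging.getLogger(__name__)

MIN_PAIR_SEPARATION_BP = 10_000_000  # planted pairs must be long-distance


@dataclass(frozen=True)
class SweepConfig:
    """One partial selective sweep: founder copying around a core variant."""

    core_variant: str
    derived_freq: float = 0.5          # fraction of haplotypes carrying the core
    recomb_rate_per_bp: float = 1e-6   # breakpoint ~ Exponential(rate) per side
    mutation_rate_per_site: float = 0.01

    def __post_init__(self):
        if not (0.0 < self.derived_freq < 1.0):
            raise ValueError(f"derived_freq must be in (0,1), got {self.derived_freq}")


@dataclass(frozen=True)
class PlantedPair:
    """A planted long-distance dosage dependence between two variants."""

    variant_a: str
    variant_b: str
    copy_error: float = 0.1   # epsilon: probability b gets a fresh HW draw

    def __post_init__(self):
        if not (0.0 <= self.copy_error <= 0.5):
            raise ValueError(f"copy_error must be in [0, 0.5], got {self.copy_error}")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_samples: int = 200
    n_chrom: int = 5
    variants_per_chrom: int = 400
    chrom_length_bp: int = 50_000_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 1000
    gene_fraction_of_window: float = 0.8  # fraction of each gene window covered
    sweeps: tuple[SweepConfig, ...] = ()
    planted_genes: tuple[str, ...] = ()
    alt_effect: float = 4.0               # mean |z| for SNPs in planted genes
    planted_module: tuple[str, ...] = ()
    module_q_in: float = 0.8              # within-module Erdos-Renyi edge prob
    ppi_edges_per_node: int = 3           # preferential-attachment m
    planted_pairs: tuple[PlantedPair, ...] = ()
    n_background_terms: int = 50

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, "
                             f"got {self.maf_range}")


# ---------------------------------------------------------------------------
# Deterministic genome layout (no randomness: positions and genes tile)
# ---------------------------------------------------------------------------

def variant_table(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced variant grid: columns variant_id, chrom, pos."""
    spacing = config.chrom_length_bp // (config.variants_per_chrom + 1)
    rows = []
    for c in range(1, config.n_chrom + 1):
        for j in range(config.variants_per_chrom):
            rows.append((f"rs{c}_{j + 1}", str(c), (j + 1) * spacing))
    return pd.DataFrame(rows, columns=["variant_id", "chrom", "pos"])


def make_gene_annotation(config: SimulationConfig) -> list[GeneAnnotation]:
    """Tile genes across chromosomes so most variants fall inside a gene."""
    per_chrom = config.n_genes // config.n_chrom
    window = config.chrom_length_bp // per_chrom
    length = int(window * config.gene_fraction_of_window)
    genes = []
    for c in range(1, config.n_chrom + 1):
        for g in range(per_chrom):
            genes.append(GeneAnnotation(gene_id=f"G{c}_{g + 1}", chrom=str(c),
                                        start=g * window + 1,
                                        end=g * window + length))
    return genes


def _core_variant_in_gene(config: SimulationConfig, gene: GeneAnnotation) -> str:
    """The variant nearest the gene's midpoint that lies inside the gene."""
    vt = variant_table(config)
    sub = vt[(vt["chrom"] == gene.chrom)
             & (vt["pos"] >= gene.start) & (vt["pos"] <= gene.end)]
    if sub.empty:
        raise ValueError(f"no variant inside gene {gene.gene_id}")
    mid = (gene.start + gene.end) // 2
    i = (sub["pos"] - mid).abs().idxmin()
    return str(vt.loc[i, "variant_id"])


def default_config(seed: int) -> SimulationConfig:
    """The default study conditions: 200 samples, 5 x 400 variants, 1,000
    genes, ~3,000 PPI edges, a 10-gene planted trait module whose genes each
    contain a partial sweep, and three planted cross-chromosome epistatic
    pairs between sweep cores.
    """
    base = SimulationConfig(seed=seed)
    genes = {g.gene_id: g for g in make_gene_annotation(base)}
    per_chrom = base.n_genes // base.n_chrom
    planted = []
    for c in range(1, base.n_chrom + 1):
        for frac in (0.25, 0.75):
            planted.append(f"G{c}_{int(per_chrom * frac)}")
    cores = [_core_variant_in_gene(base, genes[g]) for g in planted]
    # cross-chromosome pairs between sweep cores (planted genes are 2/chrom)
    pairs = (PlantedPair(cores[0], cores[3], 0.1),
             PlantedPair(cores[4], cores[7], 0.1),
             PlantedPair(cores[8], cores[1], 0.1))
    sweeps = tuple(SweepConfig(core_variant=v) for v in cores)
    return SimulationConfig(seed=seed, sweeps=sweeps,
                            planted_genes=tuple(planted),
                            planted_module=tuple(planted),
                            planted_pairs=pairs)


def null_config(seed: int, **overrides) -> SimulationConfig:
    """No sweep, no planted genes/module/pairs: pure noise for type-I checks."""
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Haplotype panel with partial sweeps
# ---------------------------------------------------------------------------

def simulate_panel(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> GenotypePanel:
    """Simulate a phased panel; sweeps plant long shared haplotypes.

    Background alleles are i.i.d. Bernoulli(freq) with freq ~ Uniform over
    ``maf_range``.  For each sweep, a fraction f of haplotypes carries the
    derived core allele; carriers copy a founder template outward from the
    core, reverting to their own independent draws beyond an
    Exponential(recomb_rate) breakpoint on each side, with per-site copy
    errors at ``mutation_rate_per_site``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    vt = variant_table(config)
    n_hap = 2 * config.n_samples
    m = len(vt)
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    hap = (rng.random((n_hap, m)) < freqs).astype(np.int8)

    index = {v: i for i, v in enumerate(vt["variant_id"])}
    positions = vt["pos"].to_numpy()
    chroms = vt["chrom"].to_numpy()
    for sweep in config.sweeps:
        if sweep.core_variant not in index:
            raise ValueError(f"sweep core {sweep.core_variant!r} not in the "
                             "variant grid")
        core = index[sweep.core_variant]
        n_carriers = int(round(sweep.derived_freq * n_hap))
        if n_carriers < 2:
            raise ValueError(
                f"sweep at {sweep.core_variant} needs >= 2 carrier haplotypes "
                f"(f * 2 * n_samples = {sweep.derived_freq * n_hap:.2f})")
        chrom_mask = chroms == chroms[core]
        chrom_cols = np.flatnonzero(chrom_mask)
        chrom_pos = positions[chrom_cols]
        core_pos = positions[core]
        founder = (rng.random(len(chrom_cols)) < freqs[chrom_cols]).astype(np.int8)
        carriers = rng.choice(n_hap, size=n_carriers, replace=False)
        hap[:, core] = 0
        for row in carriers:
            left = rng.exponential(1.0 / sweep.recomb_rate_per_bp)
            right = rng.exponential(1.0 / sweep.recomb_rate_per_bp)
            copied = ((chrom_pos >= core_pos - left)
                      & (chrom_pos <= core_pos + right))
            errors = rng.random(len(chrom_cols)) < sweep.mutation_rate_per_site
            vals = np.where(errors, 1 - founder, founder)
            hap[row, chrom_cols[copied]] = vals[copied]
        hap[carriers, core] = 1  # the derived core allele defines carriers
        hap[np.setdiff1d(np.arange(n_hap), carriers), core] = 0

    dosages = (hap[0::2] + hap[1::2]).astype(np.int8)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    return GenotypePanel(sample_ids=sample_ids, variants=vt,
                         dosages=dosages, haplotypes=hap)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(config: SimulationConfig, panel: GenotypePanel,
                           annotation: list[GeneAnnotation],
                           rng: np.random.Generator | None = None,
                           ) -> list[VariantRecord]:
    """Null-uniform GWAS p-values with planted trait genes.

    SNPs inside planted genes draw two-sided p from z ~ Normal(alt_effect, 1);
    every other SNP draws p ~ Uniform(0, 1].
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    planted = [g for g in annotation if g.gene_id in set(config.planted_genes)]
    records = []
    for row in panel.variants.itertuples(index=False):
        in_planted = any(g.chrom == row.chrom and g.start <= row.pos <= g.end
                         for g in planted)
        if in_planted:
            z = rng.normal(config.alt_effect, 1.0)
            p = max(2.0 * stats.norm.sf(abs(z)), 1e-300)
        else:
            p = 1.0 - rng.random()  # in (0, 1]
        records.append(VariantRecord(variant_id=row.variant_id, chrom=row.chrom,
                                     pos=int(row.pos), ref_allele="A",
                                     alt_allele="G", p_gwas=float(p)))
    return records


# ---------------------------------------------------------------------------
# Protein-interaction network
# ---------------------------------------------------------------------------

def simulate_ppi(config: SimulationConfig, gene_universe: list[str],
                 rng: np.random.Generator | None = None) -> nx.Graph:
    """Scale-free background (preferential attachment, m edges per node) with
    the planted module additionally wired as Erdos-Renyi(q_in)."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = len(gene_universe)
    ba_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.barabasi_albert_graph(n, config.ppi_edges_per_node, seed=ba_seed)
    g = nx.relabel_nodes(g, dict(enumerate(gene_universe)))
    module = [x for x in config.planted_module if x in set(gene_universe)]
    if len(module) != len(config.planted_module):
        raise ValueError("planted_module must be a subset of the gene universe")
    for i in range(len(module)):
        for j in range(i + 1, len(module)):
            if rng.random() < config.module_q_in:
                g.add_edge(module[i], module[j])
    return g


# ---------------------------------------------------------------------------
# GMT terms
# ---------------------------------------------------------------------------

TRUE_TERM_ID = "TERM_TRUE"


def simulate_gmt(config: SimulationConfig, gene_universe: list[str],
                 rng: np.random.Generator | None = None) -> GeneSetCollection:
    """One "true" term (the planted genes) among random background terms."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    if config.planted_genes:
        terms[TRUE_TERM_ID] = ("planted trait gene set",
                               frozenset(config.planted_genes))
    universe = np.asarray(gene_universe)
    lo = min(10, len(universe))
    hi = min(50, len(universe))
    for i in range(config.n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        terms[f"TERM_BG_{i + 1:03d}"] = ("random background term",
                                         frozenset(map(str, members)))
    return GeneSetCollection(terms=terms)


# ---------------------------------------------------------------------------
# Planted epistasis
# ---------------------------------------------------------------------------

def plant_epistasis(panel: GenotypePanel, planted_pairs: tuple[PlantedPair, ...],
                    rng: np.random.Generator | None = None,
                    seed: int | None = None) -> GenotypePanel:
    """Plant long-distance genotype dependence into a copy of the panel.

    For each planted pair, variant_b's dosage becomes variant_a's dosage with
    probability 1 - epsilon, otherwise a fresh Hardy-Weinberg draw at b's
    original allele frequency.  Haplotypes (if present) are rewritten for b
    so the dosage/haplotype consistency invariant holds; phase at b is
    arbitrary.  Pairs on the same chromosome closer than 10 Mb are rejected:
    they would be invisible to the long-distance screen.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    out = panel.copy()
    for pair in planted_pairs:
        for v in (pair.variant_a, pair.variant_b):
            if not out.has_variant(v):
                raise ValueError(f"planted pair variant {v!r} not in panel")
        chrom_a, pos_a = out.variant_position(pair.variant_a)
        chrom_b, pos_b = out.variant_position(pair.variant_b)
        if chrom_a == chrom_b and abs(pos_a - pos_b) < MIN_PAIR_SEPARATION_BP:
            raise ValueError(
                f"planted pair {pair.variant_a}/{pair.variant_b} is on one "
                f"chromosome only {abs(pos_a - pos_b)} bp apart; the "
                f"long-distance screen requires >= {MIN_PAIR_SEPARATION_BP} bp")
        ja = out._index[pair.variant_a]
        jb = out._index[pair.variant_b]
        freq_b = out.dosages[:, jb].mean() / 2.0
        copy_mask = rng.random(out.n_samples) >= pair.copy_error
        fresh = (rng.random((out.n_samples, 2)) < freq_b).sum(axis=1)
        new_b = np.where(copy_mask, out.dosages[:, ja], fresh).astype(np.int8)
        out.dosages[:, jb] = new_b
        if out.haplotypes is not None:
            h0 = np.where(new_b == 2, 1, np.where(new_b == 1, 1, 0))
            h1 = np.where(new_b == 2, 1, 0)
            out.haplotypes[0::2, jb] = h0.astype(np.int8)
            out.haplotypes[1::2, jb] = h1.astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """All in-memory inputs for one pipeline run, plus the planted truth."""

    config: SimulationConfig
    panel: GenotypePanel               # after epistasis planting
    summary_stats: list[VariantRecord]
    ihs_table: pd.DataFrame            # from the pre-epistasis swept panel
    annotation: list[GeneAnnotation]
    ppi: nx.Graph
    gmt: GeneSetCollection
    truth: dict


def generate_bundle(config: SimulationConfig) -> Bundle:
    """Generate every pipeline input from one seeded generator.

    The iHS table is computed from the swept panel *before* epistasis
    planting (mirroring the real design, where selection scores and the LD
    reference panel come from different datasets), so planted dependence
    cannot erase a core's haplotype signal.
    """
    from . import selection_screen

    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    annotation = make_gene_annotation(config)
    stats_ = simulate_summary_stats(config, panel, annotation, rng)
    ihs = selection_screen.ihs_scores(panel)
    gene_universe = [g.gene_id for g in annotation]
    ppi = simulate_ppi(config, gene_universe, rng)
    gmt = simulate_gmt(config, gene_universe, rng)
    planted_panel = plant_epistasis(panel, config.planted_pairs, rng)
    truth = {
        "planted_genes": list(config.planted_genes),
        "planted_module": list(config.planted_module),
        "planted_pairs": [[p.variant_a, p.variant_b, p.copy_error]
                          for p in config.planted_pairs],
        "sweep_cores": [s.core_variant for s in config.sweeps],
        "true_term": TRUE_TERM_ID if config.planted_genes else None,
    }
    return Bundle(config=config, panel=planted_panel, summary_stats=stats_,
                  ihs_table=ihs, annotation=annotation, ppi=ppi, gmt=gmt,
                  truth=truth)


def write_fixture_bundle(config: SimulationConfig, out_dir: str | Path,
                         ) -> dict[str, Path]:
    """Write a complete input bundle plus a truth manifest to ``out_dir``.

    Emits exactly the dialects the readers consume: VCF, summary TSV, iHS
    TSV, BED, PPI edge list, GMT, and truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config)
    paths = {
        "vcf": out / "panel.vcf",
        "summary": out / "summary_stats.tsv",
        "ihs": out / "ihs.tsv",
        "bed": out / "genes.bed",
        "ppi": out / "ppi_edges.tsv",
        "gmt": out / "terms.gmt",
        "truth": out / "truth.json",
        "config": out / "sim_config.json",
    }
    write_genotypes_vcf(bundle.panel, paths["vcf"])
    write_summary_stats(bundle.summary_stats, paths["summary"])
    write_ihs_table(bundle.ihs_table, paths["ihs"])
    write_gene_bed(bundle.annotation, paths["bed"])
    write_ppi_edges(bundle.ppi, paths["ppi"])
    write_gmt(bundle.gmt, paths["gmt"])
    paths["truth"].write_text(json.dumps(bundle.truth, indent=2))
    paths["config"].write_text(json.dumps(asdict(config), indent=2))
    logger.info("fixture bundle written to %s", out)
    return paths
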