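"""Readers and writers for every external format the pipeline touches.

All genomic coordinates are 1-based inclusive in memory; BED's 0-based
half-open convention is translated at the file boundary.  Chromosome labels
are normalized by stripping a leading ``chr``.  Readers are total: every
input line either parses or raises a located :class:`FormatError` / is
rejected with a logged, counted warning — there are no silent coercions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for missing dosage / haplotype entries


class FormatError(ValueError):
    """A structural problem in an input file (missing column, bad header...)."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = str(path) if path is not None else None
        self.line = line


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so mixed-source labels compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def _chrom_sort_key(chrom: str):
    # numeric chromosomes before lexicographic ones (X, Y, MT ...)
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """One GWAS variant: coordinates, alleles, association p, iHS score."""

    variant_id: str
    chrom: str
    pos: int                      # 1-based
    ref_allele: str = "N"
    alt_allele: str = "N"
    p_gwas: float = 1.0           # in (0, 1]
    ihs: float | None = None      # standardized iHS; None = not scored

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: pos must be >= 1, got {self.pos}")
        if not (0.0 < self.p_gwas <= 1.0):
            raise ValueError(
                f"{self.variant_id}: p_gwas must be in (0, 1], got {self.p_gwas}")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive on both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass
class GenotypePanel:
    """Reference genotypes: individuals x variants dosages, optionally phased.

    ``dosages`` counts ALT (derived) alleles, entries in {0, 1, 2} or
    ``MISSING``.  If ``haplotypes`` is present it is a (2 * n_samples,
    n_variants) binary matrix with rows 2i, 2i+1 belonging to sample i, and
    its per-sample column sums equal the dosages.
    """

    sample_ids: list[str]
    variants: pd.DataFrame            # columns: variant_id, chrom, pos
    dosages: np.ndarray               # (n_samples, n_variants) int8
    haplotypes: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self._index = {v: i for i, v in enumerate(self.variants["variant_id"])}
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples/variants")
        if self.haplotypes is not None:
            if self.haplotypes.shape != (2 * len(self.sample_ids), len(self.variants)):
                raise ValueError("haplotype matrix shape mismatch")
            hsum = self.haplotypes[0::2] + self.haplotypes[1::2]
            ok = (self.dosages == MISSING) | (hsum == self.dosages)
            if not ok.all():
                raise ValueError("haplotypes inconsistent with dosages")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant."""
        return self.dosages[:, self._index[variant_id]]

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._index

    def variant_position(self, variant_id: str) -> tuple[str, int]:
        row = self.variants.iloc[self._index[variant_id]]
        return str(row["chrom"]), int(row["pos"])

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            sample_ids=list(self.sample_ids),
            variants=self.variants.copy(),
            dosages=self.dosages.copy(),
            haplotypes=None if self.haplotypes is None else self.haplotypes.copy(),
        )


@dataclass
class GeneSetCollection:
    """GMT-style term -> (description, gene set) mapping."""

    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self):
        for term, (_, genes) in self.terms.items():
            if len(genes) == 0:
                raise ValueError(f"term {term!r} has no genes")

    def __len__(self):
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.items())

    def genes(self, term: str) -> frozenset[str]:
        return self.terms[term][1]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, (_, g) in self.terms.items():
            out |= g
        return frozenset(out)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

DEFAULT_SUMMARY_COLUMNS = {
    "variant_id": "variant_id",
    "chrom": "chrom",
    "pos": "pos",
    "p_gwas": "p_gwas",
    "ref_allele": "ref_allele",
    "alt_allele": "alt_allele",
}


def read_summary_stats(path: str | Path,
                       columns: Mapping[str, str] | None = None,
                       ) -> list[VariantRecord]:
    """Read per-variant GWAS summary statistics from a delimited text file.

    ``columns`` maps internal field names to header names in the file;
    ``variant_id``, ``chrom``, ``pos`` and ``p_gwas`` are required, allele
    columns optional.  Rows with p outside (0, 1] or non-numeric fields are
    rejected with a counted warning.  Records are returned sorted by
    (chrom, pos).
    """
    cols = dict(DEFAULT_SUMMARY_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    for key in ("variant_id", "chrom", "pos", "p_gwas"):
        if cols[key] not in df.columns:
            raise FormatError(
                f"required column {cols[key]!r} (for {key}) missing; "
                f"found {list(df.columns)}", path=path)

    records: list[VariantRecord] = []
    n_bad = 0
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        d = dict(zip(df.columns, row))
        vid = d[cols["variant_id"]]
        try:
            pos = int(d[cols["pos"]])
            p = float(d[cols["p_gwas"]])
        except (TypeError, ValueError):
            logger.warning("%s:%d non-numeric pos/p for %s; row rejected",
                           path, line_no, vid)
            n_bad += 1
            continue
        if not (0.0 < p <= 1.0):
            logger.warning("%s:%d p=%g outside (0,1] for %s; row rejected",
                           path, line_no, p, vid)
            n_bad += 1
            continue
        if vid in seen:
            logger.warning("%s:%d duplicate variant id %s; row rejected",
                           path, line_no, vid)
            n_bad += 1
            continue
        try:
            rec = VariantRecord(
                variant_id=vid,
                chrom=normalize_chrom(d[cols["chrom"]]),
                pos=pos,
                ref_allele=d.get(cols.get("ref_allele", ""), "N") or "N",
                alt_allele=d.get(cols.get("alt_allele", ""), "N") or "N",
                p_gwas=p,
            )
        except ValueError as exc:
            logger.warning("%s:%d %s; row rejected", path, line_no, exc)
            n_bad += 1
            continue
        seen.add(vid)
        records.append(rec)
    if n_bad:
        logger.warning("%s: %d rows rejected", path, n_bad)
    records.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.variant_id))
    return records


def write_summary_stats(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = [
        (r.variant_id, r.chrom, r.pos, r.ref_allele, r.alt_allele, r.p_gwas)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                     "ref_allele", "alt_allele", "p_gwas"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# iHS tables
# ---------------------------------------------------------------------------

def read_ihs_table(path: str | Path) -> pd.DataFrame:
    """Read a standardized-iHS table: variant_id, derived_freq, ihs."""
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("variant_id", "ihs"):
        if col not in df.columns:
            raise FormatError(f"iHS table missing column {col!r}", path=path)
    df["variant_id"] = df["variant_id"].astype(str)
    df["ihs"] = pd.to_numeric(df["ihs"], errors="coerce")
    return df


def write_ihs_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path: str | Path) -> GenotypePanel:
    """Read a VCF into a :class:`GenotypePanel`.

    Only biallelic SNPs are kept (others skipped with a counted warning).
    Dosage counts ALT alleles; fully phased records populate the haplotype
    matrix, any unphased genotype leaves haplotypes absent for the panel.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)

    var_rows: list[tuple[str, str, int]] = []
    dos_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    all_phased = True
    n_skipped = 0
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        dos = np.full(n, MISSING, dtype=np.int8)
        hap = np.full(2 * n, MISSING, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = gt[0], gt[1], bool(gt[2])
            if a0 < 0 or a1 < 0:
                continue
            dos[i] = a0 + a1
            hap[2 * i] = a0
            hap[2 * i + 1] = a1
            if not phased and a0 != a1:
                all_phased = False
        if (dos == MISSING).all():
            n_dropped += 1
            logger.warning("variant %s all-missing; dropped", v.ID)
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        var_rows.append((str(vid), normalize_chrom(v.CHROM), int(v.POS)))
        dos_cols.append(dos)
        hap_cols.append(hap)
    if n_skipped:
        logger.warning("%s: %d non-biallelic-SNP records skipped", path, n_skipped)
    if n_dropped:
        logger.warning("%s: %d all-missing variants dropped", path, n_dropped)

    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos"])
    order = sorted(range(len(var_rows)),
                   key=lambda i: (_chrom_sort_key(var_rows[i][1]), var_rows[i][2]))
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = (np.column_stack([dos_cols[i] for i in order])
               if order else np.zeros((n, 0), dtype=np.int8))
    haplotypes = None
    if all_phased and order:
        haplotypes = np.column_stack([hap_cols[i] for i in order])
    return GenotypePanel(sample_ids=sample_ids, variants=variants,
                         dosages=dosages, haplotypes=haplotypes)


def write_genotypes_vcf(panel: GenotypePanel, path: str | Path,
                        ref: str = "A", alt: str = "G") -> None:
    """Write a panel as VCF v4.2 (phased GTs when haplotypes are present)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        phased = panel.haplotypes is not None
        sep = "|" if phased else "/"
        for j in range(panel.n_variants):
            row = panel.variants.iloc[j]
            gts = []
            for i in range(panel.n_samples):
                if phased:
                    a0 = panel.haplotypes[2 * i, j]
                    a1 = panel.haplotypes[2 * i + 1, j]
                    gt = "./." if a0 == MISSING else f"{a0}{sep}{a1}"
                else:
                    d = panel.dosages[i, j]
                    gt = ("./." if d == MISSING
                          else {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
                gts.append(gt)
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['variant_id']}\t"
                     f"{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# BED gene annotation
# ---------------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED4+ gene annotation, converting to 1-based inclusive."""
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError("BED line needs >= 4 columns", path, line_no)
            chrom, start0, end0, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start0, end0 = int(start0), int(end0)
            except ValueError:
                raise FormatError("non-integer BED coordinates", path, line_no)
            if start0 >= end0:
                raise FormatError(
                    f"BED interval start {start0} >= end {end0}", path, line_no)
            if name in seen:
                raise FormatError(f"duplicate gene id {name!r}", path, line_no)
            seen.add(name)
            out.append(GeneAnnotation(gene_id=name, chrom=normalize_chrom(chrom),
                                      start=start0 + 1, end=end0))
    return out


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


# ---------------------------------------------------------------------------
# PPI edge list
# ---------------------------------------------------------------------------

def read_ppi_edges(path: str | Path) -> nx.Graph:
    """Read an undirected, simple protein-interaction edge list.

    Duplicate edges (in either orientation) and self-loops are dropped with
    counted warnings.
    """
    g = nx.Graph()
    n_dup = n_self = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError("edge line needs 2 gene ids", path, line_no)
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            if g.has_edge(a, b):
                n_dup += 1
                continue
            g.add_edge(a, b)
    if n_self:
        logger.warning("%s: %d self-loops dropped", path, n_self)
    if n_dup:
        logger.warning("%s: %d duplicate edges dropped", path, n_dup)
    return g


def write_ppi_edges(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: term <tab> description <tab> genes..."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    "GMT line needs term, description and >= 1 gene",
                    path, line_no)
            term, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"GMT term {term!r} has no genes", path, line_no)
            if term in terms:
                raise FormatError(f"duplicate GMT term {term!r}", path, line_no)
            terms[term] = (desc, genes)
    return GeneSetCollection(terms=terms)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in collection.terms.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Generic tab-delimited output
# ---------------------------------------------------------------------------

def write_table(records: pd.DataFrame | Sequence[Mapping], path: str | Path) -> None:
    """Write any record collection as a tab-delimited table with a header."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
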