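"""Long-distance genotypic-LD epistasis screen with FDR control.

Variants in the trait gene network are pruned for local LD (r^2 > 0.8),
paired across chromosomes or >= 10 Mb apart on the same chromosome,
filtered so at least one member is nominally trait-associated, and tested
for genotypic dependence with a permutation G-test on the joint (<= 3x3)
genotype contingency table.  Storey q-values control the FDR; pairs with
q < 0.05 are significant.  Dependence between loci too distant to be in
physical linkage is the screen's signature of epistatic co-selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypePanel, VariantRecord

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.8
LONG_RANGE_BP = 10_000_000
NOMINAL_ALPHA = 0.05
Q_THRESHOLD = 0.05
LD_N_PERM = 10_000
EXACT_N_MAX = 7            # exhaustive permutation enumeration below this
MIN_COMPLETE = 10
_G_TOL = 1e-9              # tie tolerance for G* >= G comparisons


@dataclass(frozen=True)
class LdPair:
    variant_a: str
    variant_b: str
    gene_a: str
    gene_b: str
    pair_class: str          # "inter_chromosomal" | "long_range_cis"
    distance_bp: int | None  # None for inter-chromosomal pairs
    g_stat: float
    p_ld: float
    q_ld: float
    untestable: bool = False


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def dosage_r2(a: np.ndarray, b: np.ndarray) -> float | None:
    """Squared Pearson correlation of two complete dosage vectors.

    Computed as the integer-exact ratio (n*Sab - Sa*Sb)^2 / (da * db) so the
    r^2 > threshold comparison is free of sqrt/rounding artifacts (dosage
    sums are integers, exactly representable in float64).  Returns None when
    either vector is monomorphic.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    n = len(a)
    sa, sb = int(a.sum()), int(b.sum())
    num = n * int((a * b).sum()) - sa * sb
    da = n * int((a * a).sum()) - sa * sa
    db = n * int((b * b).sum()) - sb * sb
    if da == 0 or db == 0:
        return None
    return (num * num) / (da * db)


def prune_r2(variants: list[VariantRecord], panel: GenotypePanel,
             r2_threshold: float = R2_THRESHOLD) -> list[VariantRecord]:
    """Greedy LD pruning: keep the most significant variant of each clump.

    Variants are scanned in (p_gwas, chrom, pos) order; one is kept unless
    its squared dosage correlation with an already-kept variant on the same
    chromosome is strictly above the threshold (pairwise-complete samples).
    Variants absent from the panel are dropped with a warning.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    present = [v for v in variants if panel.has_variant(v.variant_id)]
    if len(present) < len(variants):
        logger.warning("%d variants absent from the panel; dropped before "
                       "pruning", len(variants) - len(present))
    ordered = sorted(present, key=lambda v: (v.p_gwas, v.chrom, v.pos,
                                             v.variant_id))
    kept: list[VariantRecord] = []
    kept_cols: dict[str, list[np.ndarray]] = {}
    for v in ordered:
        col = panel.column(v.variant_id)
        redundant = False
        for other in kept_cols.get(v.chrom, ()):
            mask = (col != MISSING) & (other != MISSING)
            if mask.sum() < 2:
                continue
            r2 = dosage_r2(col[mask], other[mask])
            if r2 is not None and r2 > r2_threshold:
                redundant = True
                break
        if not redundant:
            kept.append(v)
            kept_cols.setdefault(v.chrom, []).append(col)
    kept.sort(key=lambda v: (v.chrom, v.pos, v.variant_id))
    logger.info("r^2 > %g pruning kept %d of %d variants", r2_threshold,
                len(kept), len(present))
    return kept


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

def candidate_pairs(pruned_variants: list[VariantRecord],
                    variant_genes: dict[str, set[str]],
                    nominal_alpha: float = NOMINAL_ALPHA,
                    long_range_bp: int = LONG_RANGE_BP,
                    ) -> list[tuple[VariantRecord, VariantRecord]]:
    """All unordered long-distance pairs passing the nominal-association filter.

    A pair qualifies when the variants sit on different chromosomes, or on
    the same chromosome >= ``long_range_bp`` apart (inclusive), and
    min(p_a, p_b) < nominal_alpha.  Pairs whose variants share a gene are
    excluded: the screen targets between-gene dependence.
    """
    vs = sorted(pruned_variants, key=lambda v: (v.chrom, v.pos, v.variant_id))
    out = []
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            a, b = vs[i], vs[j]
            if a.chrom == b.chrom and abs(a.pos - b.pos) < long_range_bp:
                continue
            if min(a.p_gwas, b.p_gwas) >= nominal_alpha:
                continue
            genes_a = variant_genes.get(a.variant_id, set())
            genes_b = variant_genes.get(b.variant_id, set())
            if genes_a & genes_b:
                continue
            out.append((a, b))
    logger.info("%d candidate long-distance pairs", len(out))
    return out


# ---------------------------------------------------------------------------
# Genotypic-LD permutation G-test
# ---------------------------------------------------------------------------

def _g_from_counts(counts: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """G = 2 sum o ln(o/e) over non-zero observed cells; vectorized over
    leading axes."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / expected)
    terms = np.where(counts > 0, terms, 0.0)
    return 2.0 * terms.sum(axis=-1)


def _joint_counts(codes: np.ndarray) -> np.ndarray:
    """Bincount 3x3 joint genotype codes for each row of a (P, n) matrix."""
    P = codes.shape[0]
    flat = codes + 9 * np.arange(P, dtype=codes.dtype)[:, None]
    return np.bincount(flat.ravel(), minlength=9 * P).reshape(P, 9).astype(float)


def genotypic_ld_test(dosages_a: np.ndarray, dosages_b: np.ndarray,
                      n_perm: int = LD_N_PERM, seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      exact: bool | None = None,
                      ) -> tuple[float, float, bool]:
    """Test independence of two genotype columns; returns (G, p, untestable).

    The G statistic is computed on the joint genotype contingency table with
    expected counts from the margins; the null distribution comes from
    permuting one locus's genotype labels across samples (add-one p).  For
    n <= 7 complete cases, exact enumeration over all distinct label
    arrangements replaces sampling (``exact`` overrides the automatic
    choice).  A locus monomorphic among complete cases is untestable:
    (0, 1, True).
    """
    a = np.asarray(dosages_a, dtype=np.int64)
    b = np.asarray(dosages_b, dtype=np.int64)
    mask = (a != MISSING) & (b != MISSING)
    a, b = a[mask], b[mask]
    n = len(a)
    if exact is None:
        exact = n <= EXACT_N_MAX
        if not exact and n < MIN_COMPLETE:
            raise ValueError(f"need >= {MIN_COMPLETE} complete samples, got {n}")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return 0.0, 1.0, True

    row = np.bincount(a, minlength=3).astype(float)
    col = np.bincount(b, minlength=3).astype(float)
    expected = np.outer(row, col).ravel() / n
    expected[expected == 0] = np.nan  # cells with a zero margin never observed
    g_obs = float(_g_from_counts(_joint_counts((3 * a + b)[None, :]),
                                 expected)[0])

    if exact:
        if n > 9:
            raise ValueError(f"exact enumeration infeasible at n={n}")
        from sympy.utilities.iterables import multiset_permutations

        g_null = np.array([
            _g_from_counts(_joint_counts((3 * a + np.asarray(perm))[None, :]),
                           expected)[0]
            for perm in multiset_permutations(sorted(b))])
        p = float(np.mean(g_null >= g_obs - _G_TOL))
        return g_obs, p, False

    if rng is None:
        rng = np.random.default_rng(seed)
    b_perm = rng.permuted(np.broadcast_to(b, (n_perm, n)).copy(), axis=1)
    g_null = _g_from_counts(_joint_counts(3 * a[None, :] + b_perm), expected)
    p = (1.0 + int(np.sum(g_null >= g_obs - _G_TOL))) / (1.0 + n_perm)
    return g_obs, float(p), False


def test_pairs(panel: GenotypePanel,
               pairs: list[tuple[VariantRecord, VariantRecord]],
               n_perm: int = LD_N_PERM, seed: int | None = None,
               ) -> pd.DataFrame:
    """Run the genotypic-LD test for every candidate pair.

    Columns: variant_a, variant_b, pair_class, distance_bp, g_stat, p_ld,
    untestable.  Untestable (monomorphic) pairs keep p = 1 and are flagged.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        g, p, untestable = genotypic_ld_test(
            panel.column(a.variant_id), panel.column(b.variant_id),
            n_perm=n_perm, rng=rng)
        if a.chrom == b.chrom:
            cls, dist = "long_range_cis", abs(a.pos - b.pos)
        else:
            cls, dist = "inter_chromosomal", None
        rows.append((a.variant_id, b.variant_id, cls, dist, g, p, untestable))
    df = pd.DataFrame(rows, columns=["variant_a", "variant_b", "pair_class",
                                     "distance_bp", "g_stat", "p_ld",
                                     "untestable"])
    n_flag = int(df["untestable"].sum()) if len(df) else 0
    if n_flag:
        logger.warning("%d pairs untestable (monomorphic locus)", n_flag)
    return df


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic regression-spline basis (intercept included); with K
    knots the basis has K columns, i.e. K - 1 df beyond the intercept."""
    K = len(knots)

    def d(k, t):
        return (np.clip(t - knots[k], 0, None) ** 3
                - np.clip(t - knots[-1], 0, None) ** 3) / (knots[-1] - knots[k])

    cols = [np.ones_like(x), x]
    for k in range(K - 2):
        cols.append(d(k, x) - d(K - 2, x))
    return np.column_stack(cols)


def estimate_pi0(p_values: np.ndarray,
                 lambdas: np.ndarray | None = None) -> float:
    """Storey pi0: pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a
    lambda grid, smoothed with a natural cubic spline (3 df) and evaluated
    at the largest lambda; capped into (0, 1]."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    knots = np.quantile(lambdas, [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0])
    basis = _natural_spline_basis(lambdas, knots)
    coef, *_ = np.linalg.lstsq(basis, pi0_l, rcond=None)
    at_max = _natural_spline_basis(np.array([lambdas[-1]]), knots) @ coef
    pi0 = float(at_max[0])
    if pi0 > 1.0:
        pi0 = 1.0
    if pi0 <= 0.0:
        logger.warning("pi0 smoother gave %.3g; falling back to 1/m", pi0)
        pi0 = 1.0 / m
    return pi0


def qvalue_estimate(p_values, small_m: int = 100,
                    pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    q_(i) is the cumulative minimum (from the largest p downward) of
    pi0 * m * p_(i) / i.  For fewer than ``small_m`` tests pi0 defaults to 1,
    which reduces the procedure to Benjamini-Hochberg; pass ``pi0``
    explicitly to override either behavior.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if pi0 is None:
        pi0 = 1.0 if m < small_m else estimate_pi0(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def significant_pairs(pair_table: pd.DataFrame,
                      q_threshold: float = Q_THRESHOLD) -> pd.DataFrame:
    """Attach q-values and keep pairs with q strictly below the threshold."""
    df = pair_table.copy()
    if df.empty:
        df["q_ld"] = pd.Series(dtype=float)
        return df
    df["q_ld"] = qvalue_estimate(df["p_ld"].to_numpy())
    sig = df[df["q_ld"] < q_threshold].reset_index(drop=True)
    logger.info("%d of %d pairs significant at q < %g", len(sig), len(df),
                q_threshold)
    return sig


# ---------------------------------------------------------------------------
# Adaptation gene set
# ---------------------------------------------------------------------------

def build_adaptation_gene_set(sig_pairs: pd.DataFrame,
                              variant_genes: dict[str, set[str]],
                              ppi: nx.Graph,
                              gene_p: dict[str, float] | None = None,
                              analysis_label: str = "trait",
                              ) -> nx.MultiGraph:
    """Annotated gene graph of the significant long-distance pairs.

    Nodes are genes carrying at least one significant-pair variant (node
    attribute ``p_gene`` when supplied); edges are (i) the significant LD
    pairs, labeled with the analysis of origin, and (ii) PPI edges among
    those genes, labeled as interaction evidence.
    """
    g = nx.MultiGraph()
    for row in sig_pairs.itertuples(index=False):
        for ga in sorted(variant_genes.get(row.variant_a, ())):
            for gb in sorted(variant_genes.get(row.variant_b, ())):
                for node in (ga, gb):
                    if node not in g:
                        g.add_node(node)
                g.add_edge(ga, gb, evidence="ld", analysis=analysis_label,
                           variant_a=row.variant_a, variant_b=row.variant_b,
                           q=row.q_ld)
    for a, b in ppi.edges():
        if a in g and b in g:
            g.add_edge(a, b, evidence="ppi")
    if gene_p:
        for node in g.nodes():
            if node in gene_p:
                g.nodes[node]["p_gene"] = gene_p[node]
    return g


def gene_set_edges_table(g: nx.MultiGraph) -> pd.DataFrame:
    rows = [(a, b, data.get("evidence"), data.get("analysis"),
             data.get("variant_a"), data.get("variant_b"), data.get("q"))
            for a, b, data in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "evidence",
                                       "analysis", "variant_a", "variant_b",
                                       "q_ld"])
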