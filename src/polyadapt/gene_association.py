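"""Gene-based association: combine SNP p-values per gene under an LD-aware
Monte-Carlo multivariate-normal null.

The observed gene statistic is T_obs = sum_j Qchi2_1(1 - p_j), the sum of
1-df chi-square quantiles of the SNP p-values.  Its null distribution under
local LD is simulated by drawing z ~ MVN(0, Sigma) from the reference-panel
SNP correlation matrix and computing T* = sum_j z_j^2; the gene p-value is
the add-one Monte-Carlo estimate (1 + #{T* >= T_obs}) / (1 + n_sims).
Single-SNP genes short-circuit to p_gene = p_snp exactly.  Gene p-values
are carried downstream as probit weights z = Phi^{-1}(1 - p) for the
dense-module search.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import MISSING, GeneAnnotation, GenotypePanel, VariantRecord

logger = logging.getLogger(__name__)

P_CLIP = 1e-16                      # keep the probit weight finite
ADAPTIVE_STAGES = (1_000, 10_000, 1_000_000)


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    n_snps: int
    t_obs: float
    p_gene: float
    z_weight: float


@dataclass
class LdMatrix:
    """Reference-panel SNP correlation matrix for one gene, repaired to PSD."""

    gene_id: str
    snp_ids: list[str]
    sigma: np.ndarray

    def __post_init__(self):
        if self.sigma.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("sigma shape does not match snp_ids")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")


# ---------------------------------------------------------------------------
# SNP -> gene assignment
# ---------------------------------------------------------------------------

def map_snps_to_genes(variants: list[VariantRecord],
                      annotation: list[GeneAnnotation],
                      flank_bp: int = 0) -> dict[str, list[VariantRecord]]:
    """Assign each variant to every gene whose (flank-extended) interval
    contains it; boundaries are inclusive.  Unassigned variants are counted.
    """
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in annotation:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_map: dict[str, list[VariantRecord]] = {}
    n_unassigned = 0
    for v in variants:
        hit = False
        for g in by_chrom.get(v.chrom, ()):
            if g.start - flank_bp <= v.pos <= g.end + flank_bp:
                gene_map.setdefault(g.gene_id, []).append(v)
                hit = True
        if not hit:
            n_unassigned += 1
    if n_unassigned:
        logger.info("%d variants mapped to no gene (flank=%d bp)",
                    n_unassigned, flank_bp)
    return gene_map


# ---------------------------------------------------------------------------
# Reference-panel LD
# ---------------------------------------------------------------------------

def _pairwise_complete_corr(cols: np.ndarray) -> np.ndarray:
    """Pearson correlation with pairwise-complete observations (MISSING
    entries excluded per pair)."""
    k = cols.shape[1]
    if k == 1:
        return np.ones((1, 1))
    if not (cols == MISSING).any():
        return np.corrcoef(cols, rowvar=False)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mask = (cols[:, i] != MISSING) & (cols[:, j] != MISSING)
            if mask.sum() < 2:
                raise ValueError("fewer than 2 complete observations for a "
                                 "SNP pair")
            r = np.corrcoef(cols[mask, i], cols[mask, j])[0, 1]
            out[i, j] = out[j, i] = r
    return out


def repair_psd(sigma: np.ndarray, floor: float = -1e-8) -> np.ndarray:
    """Clip negative eigenvalues at zero and re-normalize to unit diagonal."""
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < floor:
        logger.info("LD matrix min eigenvalue %.3g; repairing", vals.min())
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    d[d == 0] = 1.0
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


def ld_correlation_matrix(panel: GenotypePanel, snp_ids: list[str],
                          gene_id: str = "") -> LdMatrix:
    """Pairwise dosage correlations for a gene's SNPs, repaired to PSD.

    Monomorphic SNPs (undefined correlation) are dropped with a warning.
    """
    present = [s for s in snp_ids if panel.has_variant(s)]
    missing = set(snp_ids) - set(present)
    if missing:
        logger.warning("gene %s: %d SNPs absent from the panel", gene_id,
                       len(missing))
    cols = np.column_stack([panel.column(s) for s in present]).astype(float)
    keep = []
    for i, s in enumerate(present):
        col = cols[:, i]
        vals = col[col != MISSING]
        if len(vals) < 2 or np.all(vals == vals[0]):
            logger.warning("gene %s: SNP %s monomorphic in the panel; dropped",
                           gene_id, s)
            continue
        keep.append(i)
    kept_ids = [present[i] for i in keep]
    if not kept_ids:
        return LdMatrix(gene_id=gene_id, snp_ids=[], sigma=np.zeros((0, 0)))
    corr = _pairwise_complete_corr(cols[:, keep])
    return LdMatrix(gene_id=gene_id, snp_ids=kept_ids, sigma=repair_psd(corr))


# ---------------------------------------------------------------------------
# Monte-Carlo gene test
# ---------------------------------------------------------------------------

def _simulate_null_t(chol: np.ndarray, n_sims: int,
                     rng: np.random.Generator) -> np.ndarray:
    k = chol.shape[0]
    # chunked so 10^6-replicate escalations stay within modest memory
    chunk = max(1, min(n_sims, 4_000_000 // max(k, 1)))
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        b = min(chunk, n_sims - done)
        z = rng.standard_normal((b, k)) @ chol.T
        out[done:done + b] = np.einsum("ij,ij->i", z, z)
        done += b
    return out


def gene_test_mc(snp_ps: list[float], sigma: LdMatrix | np.ndarray,
                 n_sims: int = ADAPTIVE_STAGES[0], seed: int | None = None,
                 adaptive: bool = True,
                 max_sims: int = ADAPTIVE_STAGES[-1]) -> tuple[float, float]:
    """Monte-Carlo gene p-value: returns (t_obs, p_gene).

    With ``adaptive`` the simulation escalates through the staging
    1e3 -> 1e4 -> 1e6 while the current estimate sits below 10x the stage's
    resolution, so small p-values get enough replicates without spending
    them everywhere.  With ``adaptive=False`` exactly ``n_sims`` replicates
    are used.
    """
    ps = np.asarray(snp_ps, dtype=float)
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("SNP p-values must be in (0, 1]")
    mat = sigma.sigma if isinstance(sigma, LdMatrix) else np.asarray(sigma)
    if len(ps) != mat.shape[0]:
        raise ValueError(f"{len(ps)} p-values but sigma is {mat.shape}")
    t_obs = float(np.sum(stats.chi2.isf(ps, df=1)))
    if len(ps) == 1:
        return t_obs, float(ps[0])  # exact single-SNP shortcut

    vals = np.linalg.eigvalsh(mat)
    if vals.min() < -1e-8:
        raise ValueError(f"sigma not PSD after repair (min eig {vals.min():.3g})")
    chol = np.linalg.cholesky(mat + 1e-10 * np.eye(mat.shape[0]))
    rng = np.random.default_rng(seed)

    if adaptive:
        stages = [s for s in ADAPTIVE_STAGES if s <= max_sims] or [max_sims]
    else:
        stages = [max(int(n_sims), 1)]
    p_gene = 1.0
    for i, n in enumerate(stages):
        t_null = _simulate_null_t(chol, n, rng)
        p_gene = (1.0 + np.sum(t_null >= t_obs)) / (1.0 + n)
        resolution = 1.0 / (1.0 + n)
        if not (adaptive and i + 1 < len(stages) and p_gene < 10.0 * resolution):
            break
    return t_obs, float(p_gene)


def probit_weight(p_gene: float) -> float:
    """Node weight z = Phi^{-1}(1 - p), with p clipped away from {0, 1}."""
    if not (0.0 < p_gene <= 1.0):
        raise ValueError(f"p_gene must be in (0, 1], got {p_gene}")
    p = min(max(p_gene, P_CLIP), 1.0 - P_CLIP)
    return float(stats.norm.isf(p))


# ---------------------------------------------------------------------------
# Whole-panel driver
# ---------------------------------------------------------------------------

def score_genes(gene_map: dict[str, list[VariantRecord]], panel: GenotypePanel,
                n_sims: int = ADAPTIVE_STAGES[0], seed: int | None = None,
                adaptive: bool = True,
                max_sims: int = ADAPTIVE_STAGES[-1]) -> list[GeneScore]:
    """Run the Monte-Carlo gene test for every gene with >= 1 screened SNP.

    Genes whose SNPs are all absent from the panel or monomorphic are
    skipped with a warning (they cannot be calibrated); genes with zero
    screened SNPs are simply absent from the input map and hence the output.
    """
    ss = np.random.SeedSequence(seed)
    scores: list[GeneScore] = []
    for gene_id in sorted(gene_map):
        variants = gene_map[gene_id]
        ld = ld_correlation_matrix(panel, [v.variant_id for v in variants],
                                   gene_id=gene_id)
        if not ld.snp_ids:
            logger.warning("gene %s: no testable SNPs in the panel; skipped",
                           gene_id)
            continue
        p_by_id = {v.variant_id: v.p_gwas for v in variants}
        ps = [p_by_id[s] for s in ld.snp_ids]
        # deterministic per-gene stream independent of iteration order
        # (crc32, not hash(): str hashing is randomized per process)
        gene_key = zlib.crc32(gene_id.encode()) & 0x7FFFFFFF
        gene_seed = int(np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(gene_key,)
        ).generate_state(1)[0] % (2**31))
        t_obs, p_gene = gene_test_mc(ps, ld, n_sims=n_sims, seed=gene_seed,
                                     adaptive=adaptive, max_sims=max_sims)
        scores.append(GeneScore(gene_id=gene_id, n_snps=len(ld.snp_ids),
                                t_obs=t_obs, p_gene=p_gene,
                                z_weight=probit_weight(p_gene)))
    return scores


def gene_scores_table(scores: list[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.n_snps, s.t_obs, s.p_gene, s.z_weight) for s in scores],
        columns=["gene_id", "n_snps", "t_obs", "p_gene", "z_weight"])
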