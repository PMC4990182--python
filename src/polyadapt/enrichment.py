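"""Hypergeometric (one-sided Fisher exact) term enrichment with Bonferroni
adjustment of the adaptation gene set against GMT term collections."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

MIN_OVERLAP = 2


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    overlap_genes: frozenset[str]
    a: int            # overlap count
    n: int            # study size
    K: int            # term size within background
    N: int            # background size
    p_fisher: float
    p_bonferroni: float


def fisher_term_test(study_genes: set[str], term_genes: set[str],
                     background_genes: set[str]) -> float:
    """Upper-tail hypergeometric p: P(X >= a), X ~ Hypergeom(N, K, n).

    The term is intersected with the background before testing; the study
    set must be a subset of the background.
    """
    study = set(study_genes)
    background = set(background_genes)
    if not study:
        raise ValueError("empty study set")
    if not background:
        raise ValueError("empty background set")
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    term = set(term_genes) & background
    a = len(study & term)
    return float(stats.hypergeom.sf(a - 1, len(background), len(term),
                                    len(study)))


def enrich_gene_set(study_genes: set[str], gmt: GeneSetCollection,
                    background_genes: set[str],
                    min_overlap: int = MIN_OVERLAP) -> list[EnrichmentResult]:
    """Test every term with >= ``min_overlap`` study genes; Bonferroni-adjust
    by the number of terms actually tested; sort by adjusted p (term-id
    tie-break)."""
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    study = set(study_genes) & set(background_genes)
    background = set(background_genes)
    candidates = []
    for term_id, (desc, genes) in gmt:
        term = set(genes) & background
        overlap = study & term
        if len(overlap) < min_overlap:
            continue
        candidates.append((term_id, desc, term, overlap))
    m_tested = len(candidates)
    results = []
    for term_id, desc, term, overlap in candidates:
        p = fisher_term_test(study, term, background)
        results.append(EnrichmentResult(
            term_id=term_id, description=desc,
            overlap_genes=frozenset(overlap), a=len(overlap), n=len(study),
            K=len(term), N=len(background), p_fisher=p,
            p_bonferroni=min(1.0, p * m_tested)))
    results.sort(key=lambda r: (r.p_bonferroni, r.p_fisher, r.term_id))
    logger.info("%d terms tested (min overlap %d)", m_tested, min_overlap)
    return results


def enrichment_table(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [(r.term_id, r.description, ",".join(sorted(r.overlap_genes)), r.a,
          r.n, r.K, r.N, r.p_fisher, r.p_bonferroni) for r in results],
        columns=["term_id", "description", "overlap_genes", "a", "n", "K",
                 "N", "p_fisher", "p_bonferroni"])
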