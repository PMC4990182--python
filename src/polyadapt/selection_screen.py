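"""Haplotype-based selection screen: EHH, iHH, iHS, and |iHS| filtering.

The integrated haplotype score (iHS) contrasts the decay of extended
haplotype homozygosity (EHH) around a core SNP between carriers of the
ancestral and derived alleles.  A recent positive sweep leaves unusually
long haplotypes around the swept (derived) allele, so |iHS| is large at
selected, non-fixed loci.  Scores are standardized within derived-allele
frequency bins so that |iHS| is comparable across frequencies.

The pipeline can either ingest a precomputed standardized-iHS table or
compute scores from a phased panel (used for fully synthetic runs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypePanel, VariantRecord

logger = logging.getLogger(__name__)

EHH_CUTOFF = 0.05        # stop integrating once EHH falls below this
N_FREQ_BINS = 20         # equal-width derived-frequency bins for standardization
MIN_CARRIERS = 2         # EHH needs at least one haplotype pair


@dataclass(frozen=True)
class IhsScore:
    variant_id: str
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    ihs_unstandardized: float      # ln(iHH_A / iHH_D)
    ihs: float | None              # standardized within frequency bin
    edge_truncated: bool = False


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def ehh(haplotypes: np.ndarray, core_index: int, target_index: int) -> float:
    """Extended haplotype homozygosity over the span core..target inclusive.

    ``haplotypes`` holds only carriers of one core allele (rows).  EHH is the
    probability that two distinct carrier haplotypes are identical over the
    span: sum over distinct haplotype strings g of C(n_g, 2) / C(n, 2).
    """
    hap = np.asarray(haplotypes)
    n = hap.shape[0]
    if n < MIN_CARRIERS:
        raise ValueError(f"EHH needs >= {MIN_CARRIERS} carrier haplotypes, got {n}")
    lo, hi = sorted((core_index, target_index))
    span = hap[:, lo:hi + 1]
    _, counts = np.unique(span, axis=0, return_counts=True)
    pairs_same = np.sum(counts * (counts - 1)) / 2.0
    pairs_total = n * (n - 1) / 2.0
    return float(pairs_same / pairs_total)


def _ehh_curve_one_side(hap: np.ndarray, positions: np.ndarray, core: int,
                        step: int, cutoff: float) -> tuple[list[tuple[int, float]], bool]:
    """Walk outward from the core, extending haplotype groups incrementally.

    Returns the (distance_bp, EHH) curve starting at (0, 1.0) and a flag set
    when the chromosome end is reached before EHH drops below the cutoff.
    Groups are refined one marker at a time (new_group = 2*old + allele),
    which makes EHH non-increasing by construction.
    """
    n_sites = hap.shape[1]
    n = hap.shape[0]
    pairs_total = n * (n - 1) / 2.0
    core_pos = positions[core]
    curve: list[tuple[int, float]] = [(0, 1.0)]
    groups = np.zeros(n, dtype=np.int64)
    j = core + step
    while 0 <= j < n_sites:
        combo = groups * 2 + hap[:, j]
        _, groups = np.unique(combo, return_inverse=True)
        counts = np.bincount(groups)
        e = float(np.sum(counts * (counts - 1)) / 2.0 / pairs_total)
        curve.append((int(abs(positions[j] - core_pos)), e))
        if e < cutoff:
            return curve, False
        j += step
    return curve, True  # ran off the chromosome while EHH >= cutoff


# ---------------------------------------------------------------------------
# iHH
# ---------------------------------------------------------------------------

def ihh(ehh_curves: list[list[tuple[float, float]]], cutoff: float = EHH_CUTOFF,
        ) -> tuple[float, bool]:
    """Integrate EHH over distance (trapezoid rule), summed over sides.

    Each curve starts at (0, 1.0) with strictly increasing distances.
    Integration is truncated at the first marker where EHH < cutoff; the
    final trapezoid between the last marker >= cutoff and that first
    sub-cutoff marker is included.  Returns (area, edge_truncated) where the
    flag is set when any side's curve never reaches the cutoff (the core sat
    too close to a chromosome edge to finish the integral).
    """
    total = 0.0
    edge = False
    for curve in ehh_curves:
        if not curve:
            edge = True
            continue
        d0, e0 = curve[0]
        if d0 != 0 or e0 != 1.0:
            raise ValueError("EHH curve must start at (0, 1.0)")
        reached_cutoff = False
        for (da, ea), (db, eb) in zip(curve, curve[1:]):
            if db <= da:
                raise ValueError("EHH curve distances must be strictly increasing")
            total += (ea + eb) / 2.0 * (db - da)
            if eb < cutoff:
                reached_cutoff = True
                break
        if not reached_cutoff:
            edge = True
    return total, edge


# ---------------------------------------------------------------------------
# Per-variant unstandardized iHS from a phased panel
# ---------------------------------------------------------------------------

def ihs_unstandardized_scores(panel: GenotypePanel, cutoff: float = EHH_CUTOFF,
                              min_carriers: int = MIN_CARRIERS) -> pd.DataFrame:
    """Compute ln(iHH_ancestral / iHH_derived) for every scorable variant.

    A variant is scorable when both allele classes have at least
    ``min_carriers`` haplotypes and both iHH integrals are positive.  The
    derived allele is haplotype state 1 (ALT).  Columns: variant_id,
    derived_freq, ihh_ancestral, ihh_derived, ihs_unstandardized,
    edge_truncated.
    """
    if panel.haplotypes is None:
        raise ValueError("iHS computation requires phased haplotypes")
    hap_all = panel.haplotypes
    rows = []
    for chrom, idx in panel.variants.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        positions = panel.variants["pos"].to_numpy()[idx]
        hap = hap_all[:, idx]
        complete = ~(hap == MISSING).any(axis=1)
        hap = hap[complete]
        for local_core in range(len(idx)):
            col = hap[:, local_core]
            carriers_d = hap[col == 1]
            carriers_a = hap[col == 0]
            if len(carriers_d) < min_carriers or len(carriers_a) < min_carriers:
                continue
            freq = len(carriers_d) / (len(carriers_d) + len(carriers_a))
            edge = False
            areas = []
            for carriers in (carriers_a, carriers_d):
                curves = []
                for step in (-1, 1):
                    c, hit_edge = _ehh_curve_one_side(
                        carriers, positions, local_core, step, cutoff)
                    edge = edge or hit_edge
                    curves.append(c)
                area, _ = ihh(curves, cutoff=cutoff)
                areas.append(area)
            ihh_a, ihh_d = areas
            if ihh_a <= 0 or ihh_d <= 0:
                continue
            rows.append((panel.variants["variant_id"].iloc[idx[local_core]],
                         freq, ihh_a, ihh_d, math.log(ihh_a / ihh_d), edge))
    return pd.DataFrame(rows, columns=["variant_id", "derived_freq",
                                       "ihh_ancestral", "ihh_derived",
                                       "ihs_unstandardized", "edge_truncated"])


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def ihs_standardize(scores: pd.DataFrame, n_bins: int = N_FREQ_BINS,
                    min_bin_size: int = 3) -> pd.DataFrame:
    """Standardize unstandardized iHS within equal-width derived-freq bins.

    Within each bin the mean is subtracted and the sample SD (ddof=1)
    divides.  Scores in bins with fewer than ``min_bin_size`` members, or in
    bins with zero SD, are flagged unstandardizable (ihs = NaN) and excluded
    downstream with a logged count.
    """
    df = scores.copy()
    freq = df["derived_freq"].to_numpy(dtype=float)
    raw = df["ihs_unstandardized"].to_numpy(dtype=float)
    bins = np.clip((freq * n_bins).astype(int), 0, n_bins - 1)
    ihs = np.full(len(df), np.nan)
    n_flagged = 0
    for b in np.unique(bins):
        mask = bins == b
        vals = raw[mask]
        if mask.sum() < min_bin_size:
            n_flagged += int(mask.sum())
            continue
        sd = vals.std(ddof=1)
        if sd == 0 or np.ptp(vals) == 0:  # all-equal bins: SD is pure roundoff
            n_flagged += int(mask.sum())
            continue
        ihs[mask] = (vals - vals.mean()) / sd
    if n_flagged:
        logger.warning("%d iHS scores unstandardizable (sparse or degenerate "
                       "frequency bins)", n_flagged)
    df["ihs"] = ihs
    return df


def ihs_scores(panel: GenotypePanel, cutoff: float = EHH_CUTOFF,
               n_bins: int = N_FREQ_BINS, drop_edge_truncated: bool = False,
               ) -> pd.DataFrame:
    """Full iHS computation from a phased panel: iHH per allele, log-ratio,
    frequency-bin standardization.  Set ``drop_edge_truncated`` to discard
    cores whose EHH never decayed below the cutoff before a chromosome end.
    """
    raw = ihs_unstandardized_scores(panel, cutoff=cutoff)
    if drop_edge_truncated and len(raw):
        n_edge = int(raw["edge_truncated"].sum())
        if n_edge:
            logger.warning("%d edge-truncated iHS scores dropped", n_edge)
        raw = raw[~raw["edge_truncated"]].reset_index(drop=True)
    if raw.empty:
        return raw.assign(ihs=pd.Series(dtype=float))
    return ihs_standardize(raw, n_bins=n_bins)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def attach_ihs(variants: list[VariantRecord], ihs_table: pd.DataFrame,
               match_by: str = "id") -> list[VariantRecord]:
    """Attach standardized iHS scores to GWAS variants.

    ``match_by`` is "id" (rsID-style identifiers; default) or "position"
    (chrom:pos keys, for sources with divergent identifiers).
    """
    from dataclasses import replace

    if match_by == "id":
        lookup = dict(zip(ihs_table["variant_id"].astype(str), ihs_table["ihs"]))
        key = lambda v: v.variant_id
    elif match_by == "position":
        if not {"chrom", "pos"} <= set(ihs_table.columns):
            raise ValueError("position matching requires chrom/pos columns "
                             "in the iHS table")
        lookup = {f"{c}:{p}": s for c, p, s in zip(
            ihs_table["chrom"].astype(str), ihs_table["pos"].astype(int),
            ihs_table["ihs"])}
        key = lambda v: f"{v.chrom}:{v.pos}"
    else:
        raise ValueError(f"match_by must be 'id' or 'position', got {match_by!r}")

    out = []
    for v in variants:
        s = lookup.get(key(v))
        if s is not None and not (isinstance(s, float) and math.isnan(s)):
            out.append(replace(v, ihs=float(s)))
        else:
            out.append(replace(v, ihs=None))
    return out


def filter_by_ihs(variants: list[VariantRecord], threshold: float = 1.5,
                  ) -> list[VariantRecord]:
    """Keep variants with |iHS| strictly greater than the threshold.

    Variants without an iHS score are dropped with a counted warning (not
    every GWAS variant is scored by the selection scan).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    n_missing = sum(1 for v in variants if v.ihs is None)
    kept = [v for v in variants if v.ihs is not None and abs(v.ihs) > threshold]
    if n_missing:
        logger.warning("%d variants lacked an iHS score and were dropped "
                       "before screening", n_missing)
    logger.info("|iHS| > %g screen: %d of %d scored variants kept",
                threshold, len(kept), len(variants) - n_missing)
    if not kept:
        logger.warning("no variants pass the |iHS| screen")
    return kept
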