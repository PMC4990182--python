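"""Dense-module search on the protein-interaction network.

Each scored gene seeds a greedy search: at every step the scored direct
neighbors of the current module are evaluated and the one maximizing the
module score Z_m = sum(z_i) / sqrt(k) is added, but only if the new score
exceeds the old by more than the factor (1 + r).  Raw module scores are
normalized against random k-subsets of all scored genes (connectivity is
not required in the null), giving Z_N = (Z_m - mean Z*) / sd Z*.  The
top-ranked modules by Z_N are merged into the trait gene network.

Interactors without a gene score are invisible to the search: they can
neither seed nor join a module.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .gene_association import GeneScore

logger = logging.getLogger(__name__)

DEFAULT_R = 0.1            # required proportional score improvement per step
DEFAULT_N_TOP = 10         # modules merged into the trait gene network
DEFAULT_N_PERM = 100_000   # random gene sets for score normalization
EXHAUSTIVE_LIMIT = 10_000  # enumerate all k-subsets when feasible


@dataclass
class Module:
    seed_gene: str
    genes: list[str]                   # insertion order
    z_m: float
    z_n: float | None = None
    trace: list[float] = field(default_factory=list)  # Z_m after each step

    @property
    def k(self) -> int:
        return len(self.genes)


def module_score(weights: list[float] | np.ndarray) -> float:
    """Z_m = sum(z_i) / sqrt(k)."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValueError("module_score needs at least one weight")
    return float(w.sum() / math.sqrt(w.size))


# ---------------------------------------------------------------------------
# Greedy growth
# ---------------------------------------------------------------------------

def grow_module(network: nx.Graph, weights: dict[str, float], seed_gene: str,
                r: float = DEFAULT_R, d: int = 1) -> Module:
    """Grow a module greedily from one seed.

    Candidates are the scored genes within graph distance ``d`` of the
    current module (d = 1, the default, means direct neighbors; d > 1
    candidates are attached together with a shortest connecting path of
    scored genes so the module stays connected).  Ties are broken
    deterministically: higher z_weight first, then lexicographic gene id.
    """
    if seed_gene not in weights:
        raise ValueError(f"seed gene {seed_gene!r} has no score")
    if seed_gene not in network:
        raise ValueError(f"seed gene {seed_gene!r} not in the network")
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r}")
    scored = lambda g: g in weights

    members: list[str] = [seed_gene]
    member_set = {seed_gene}
    z = module_score([weights[seed_gene]])
    trace = [z]
    while True:
        candidates = _candidates(network, member_set, weights, d)
        best: tuple[float, float, str, list[str]] | None = None
        for gene, path in candidates.items():
            addition = [g for g in path if g not in member_set]
            new_z = module_score([weights[g] for g in members] +
                                 [weights[g] for g in addition])
            key = (new_z, weights[gene], gene)
            if best is None or (key[0], key[1], _neg_lex(key[2])) > (
                    best[0], best[1], _neg_lex(best[2])):
                best = (new_z, weights[gene], gene, addition)
        if best is None:
            break
        new_z, _, _, addition = best
        if not (new_z > z * (1.0 + r)):
            break
        members.extend(addition)
        member_set.update(addition)
        z = new_z
        trace.append(z)
    return Module(seed_gene=seed_gene, genes=members, z_m=z, trace=trace)


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


def _candidates(network: nx.Graph, member_set: set[str],
                weights: dict[str, float], d: int) -> dict[str, list[str]]:
    """Scored genes within distance d of the module, with the scored-gene
    path (excluding module members) used to attach each one."""
    if d == 1:
        out = {}
        for m in member_set:
            for nb in network.neighbors(m):
                if nb not in member_set and nb in weights:
                    out[nb] = [nb]
        return out
    # BFS through scored genes only, up to depth d
    out: dict[str, list[str]] = {}
    frontier = {m: [] for m in member_set}
    visited = set(member_set)
    for _ in range(d):
        nxt: dict[str, list[str]] = {}
        for node, path in frontier.items():
            for nb in network.neighbors(node):
                if nb in visited or nb not in weights:
                    continue
                visited.add(nb)
                nxt[nb] = path + [nb]
        out.update(nxt)
        frontier = nxt
    return out


# ---------------------------------------------------------------------------
# Null normalization
# ---------------------------------------------------------------------------

def _null_moments(all_weights: np.ndarray, k: int, n_perm: int,
                  rng: np.random.Generator) -> tuple[float, float]:
    """Mean and sample SD of Z* over random k-subsets of the score universe.

    Exhaustive enumeration replaces sampling when C(universe, k) is small
    enough; otherwise k-subsets are drawn uniformly (chunked argpartition of
    random keys, one key per gene per draw).
    """
    n = len(all_weights)
    if k > n:
        raise ValueError(f"module size {k} exceeds the score universe {n}")
    if math.comb(n, k) <= EXHAUSTIVE_LIMIT:
        zs = np.array([sum(c) for c in
                       itertools.combinations(all_weights, k)]) / math.sqrt(k)
        if len(zs) < 2:
            raise ValueError("degenerate null: only one possible gene set")
    else:
        zs = np.empty(n_perm)
        done = 0
        chunk = max(1, min(n_perm, 20_000_000 // n))
        while done < n_perm:
            b = min(chunk, n_perm - done)
            keys = rng.random((b, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            zs[done:done + b] = all_weights[idx].sum(axis=1) / math.sqrt(k)
            done += b
    sd = float(zs.std(ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate score universe: null SD is zero")
    return float(zs.mean()), sd


def normalize_score(module: Module, all_weights: list[float] | np.ndarray,
                    n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                    rng: np.random.Generator | None = None) -> float:
    """Z_N = (Z_m - mean Z*) / sd Z* against random k-subset null scores."""
    w = np.asarray(all_weights, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    mean, sd = _null_moments(w, module.k, n_perm, rng)
    return float((module.z_m - mean) / sd)


# ---------------------------------------------------------------------------
# Search and selection
# ---------------------------------------------------------------------------

def search_and_select(network: nx.Graph, gene_scores: list[GeneScore],
                      r: float = DEFAULT_R, n_top: int = DEFAULT_N_TOP,
                      n_perm: int = DEFAULT_N_PERM, seed: int | None = None,
                      d: int = 1) -> tuple[list[Module], set[str]]:
    """Grow a module from every scored gene on the network, normalize,
    deduplicate, and return the top ``n_top`` modules plus the union of
    their genes (the trait gene network).

    Null moments are computed once per module size k (the random-set null
    depends only on k), with one deterministic substream per k, so results
    do not depend on input ordering.
    """
    weights = {s.gene_id: s.z_weight for s in gene_scores}
    seeds = sorted(g for g in weights if g in network)
    if not seeds:
        raise ValueError("no scored genes are present on the network")
    dropped = len(weights) - len(seeds)
    if dropped:
        logger.info("%d scored genes absent from the PPI network", dropped)

    modules: list[Module] = []
    seen: set[frozenset[str]] = set()
    for s in seeds:
        mod = grow_module(network, weights, s, r=r, d=d)
        key = frozenset(mod.genes)
        if key in seen:
            continue
        seen.add(key)
        modules.append(mod)

    all_w = np.asarray([weights[g] for g in sorted(weights)])
    ss = np.random.SeedSequence(seed)
    moments: dict[int, tuple[float, float]] = {}
    for mod in modules:
        if mod.k not in moments:
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=ss.entropy, spawn_key=(mod.k,)))
            moments[mod.k] = _null_moments(all_w, mod.k, n_perm, rng)
        mean, sd = moments[mod.k]
        mod.z_n = float((mod.z_m - mean) / sd)

    modules.sort(key=lambda m: (-m.z_n, -m.z_m, m.seed_gene))
    top = modules[:n_top]
    union = set().union(*(m.genes for m in top))
    logger.info("top-%d modules merged into a %d-gene trait network",
                len(top), len(union))
    return top, union


def modules_table(modules: list[Module]):
    import pandas as pd

    return pd.DataFrame(
        [(m.seed_gene, m.k, ",".join(m.genes), m.z_m, m.z_n) for m in modules],
        columns=["seed_gene", "k", "genes", "z_m", "z_n"])
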