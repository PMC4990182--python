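import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from polyadapt import epistasis_ld as eld
from polyadapt.io_formats import VariantRecord

from conftest import make_panel


def v(vid, chrom, pos, p=0.5):
    return VariantRecord(vid, chrom, pos, p_gwas=p)


class TestPruneR2:
    def test_identical_columns_keep_smaller_p(self):
        panel = make_panel({"a": [0, 1, 2, 1, 0], "b": [0, 1, 2, 1, 0]})
        kept = eld.prune_r2([v("a", "1", 100, p=0.01),
                             v("b", "1", 200, p=0.5)], panel)
        assert [x.variant_id for x in kept] == ["a"]

    def test_r2_exactly_at_threshold_keeps_both(self):
        # r^2 = 144/180 = 0.8 exactly: strict > keeps the pair
        panel = make_panel({"a": [0, 0, 0, 1, 1, 1], "b": [0, 0, 0, 1, 1, 2]})
        kept = eld.prune_r2([v("a", "1", 100, p=0.01),
                             v("b", "1", 200, p=0.5)], panel,
                            r2_threshold=0.8)
        assert len(kept) == 2

    def test_greedy_chain(self, rng):
        # a~b and b~c correlated above threshold, a~c below: keep {a, c}
        base = rng.integers(0, 3, 400)
        flip = lambda x, k: np.where(rng.random(400) < k,
                                     rng.integers(0, 3, 400), x)
        b = flip(base, 0.02)
        c = flip(b, 0.6)
        panel = make_panel({"a": base, "b": b, "c": c})
        r2ab = eld.dosage_r2(base, b)
        r2bc = eld.dosage_r2(b, c)
        r2ac = eld.dosage_r2(base, c)
        assert r2ab > 0.8 and r2bc < 0.8 and r2ac < 0.8
        kept = eld.prune_r2([v("a", "1", 100, p=0.01), v("b", "1", 200, p=0.1),
                             v("c", "1", 300, p=0.2)], panel)
        assert [x.variant_id for x in kept] == ["a", "c"]

    def test_different_chromosomes_never_pruned(self):
        panel = make_panel({"a": [0, 1, 2, 1], "b": [0, 1, 2, 1]},
                           chroms={"a": "1", "b": "2"})
        kept = eld.prune_r2([v("a", "1", 100, p=0.01),
                             v("b", "2", 100, p=0.5)], panel)
        assert len(kept) == 2

    def test_absent_variant_dropped(self):
        panel = make_panel({"a": [0, 1, 2, 1]})
        kept = eld.prune_r2([v("a", "1", 100), v("ghost", "1", 200)], panel)
        assert [x.variant_id for x in kept] == ["a"]


class TestCandidatePairs:
    GENEMAP = {"a": {"GA"}, "b": {"GB"}, "c": {"GC"}, "d": {"GA"}}

    def test_ten_megabase_boundary_inclusive(self):
        pairs = eld.candidate_pairs(
            [v("a", "1", 1, p=0.01), v("b", "1", 10_000_001, p=0.5)],
            self.GENEMAP)
        assert len(pairs) == 1

    def test_below_ten_megabases_excluded(self):
        pairs = eld.candidate_pairs(
            [v("a", "1", 1, p=0.01), v("b", "1", 10_000_000, p=0.5)],
            self.GENEMAP)
        assert pairs == []

    def test_nominal_filter(self):
        pairs = eld.candidate_pairs(
            [v("a", "1", 1, p=0.2), v("b", "2", 1, p=0.2)], self.GENEMAP)
        assert pairs == []
        pairs = eld.candidate_pairs(
            [v("a", "1", 1, p=0.049), v("b", "2", 1, p=0.2)], self.GENEMAP)
        assert len(pairs) == 1

    def test_same_gene_pairs_excluded(self):
        pairs = eld.candidate_pairs(
            [v("a", "1", 1, p=0.01), v("d", "2", 1, p=0.01)], self.GENEMAP)
        assert pairs == []


class TestGenotypicLdTest:
    def test_perfect_dependence_minimal_p(self, rng):
        a = rng.integers(0, 3, 50)
        g, p, untestable = eld.genotypic_ld_test(a, a.copy(), n_perm=1000,
                                                 seed=0)
        assert not untestable
        assert p == pytest.approx(1 / 1001, abs=2e-3)

    def test_monomorphic_locus_untestable(self):
        a = np.ones(20, dtype=int)
        b = np.arange(20) % 3
        g, p, untestable = eld.genotypic_ld_test(a, b, n_perm=100, seed=0)
        assert untestable and p == 1.0

    def test_g_invariant_under_consistent_relabeling(self, rng):
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        g1, _, _ = eld.genotypic_ld_test(a, b, n_perm=200, seed=0)
        g2, _, _ = eld.genotypic_ld_test(2 - a, 2 - b, n_perm=200, seed=0)
        assert g1 == pytest.approx(g2, abs=1e-9)

    def test_exact_enumeration_matches_mc(self):
        a = np.array([0, 1, 2, 0, 1, 2])
        b = np.array([0, 1, 2, 2, 1, 0])
        g_e, p_exact, _ = eld.genotypic_ld_test(a, b)  # auto-exact at n=6
        n_perm = 20_000
        g_m, p_mc, _ = eld.genotypic_ld_test(a, b, exact=False,
                                             n_perm=n_perm, seed=11)
        assert g_e == pytest.approx(g_m)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 3 * se + 2 / n_perm

    def test_missing_dosages_excluded(self, rng):
        a = rng.integers(0, 3, 40)
        b = a.copy()
        a[:5] = -1
        g, p, untestable = eld.genotypic_ld_test(a, b, n_perm=500, seed=0)
        assert not untestable and p < 0.05


class TestQvalues:
    def test_hand_benjamini_hochberg(self):
        q = eld.qvalue_estimate([0.01, 0.02, 0.03, 0.9])
        assert list(q) == pytest.approx([0.04, 0.04, 0.04, 0.9])

    def test_all_ones(self):
        assert list(eld.qvalue_estimate([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    def test_monotone_in_p(self, rng):
        p = rng.uniform(0.001, 1.0, 500)
        q = eld.qvalue_estimate(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_pi0_reduces_q_under_signal(self, rng):
        # heavy true-signal mixture: Storey pi0 < 1 gives q <= BH q
        p = np.concatenate([rng.uniform(0, 0.001, 60),
                            rng.uniform(0, 1, 140)])
        q_storey = eld.qvalue_estimate(p, small_m=10)
        q_bh = eld.qvalue_estimate(p, pi0=1.0)
        assert (q_storey <= q_bh + 1e-12).all()

    def test_empty_input(self):
        assert eld.qvalue_estimate([]).size == 0

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_matches_benjamini_hochberg_oracle(self, ps):
        # pi0 = 1 reduces the procedure to BH (statsmodels as oracle)
        q = eld.qvalue_estimate(ps, pi0=1.0)
        _, q_bh, _, _ = multipletests(ps, method="fdr_bh")
        assert q == pytest.approx(q_bh, abs=1e-12)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            eld.qvalue_estimate([0.0, 0.5])


class TestSignificantPairs:
    def _table(self, ps):
        return pd.DataFrame({
            "variant_a": [f"a{i}" for i in range(len(ps))],
            "variant_b": [f"b{i}" for i in range(len(ps))],
            "pair_class": "inter_chromosomal", "distance_bp": None,
            "g_stat": 1.0, "p_ld": ps, "untestable": False})

    def test_q_exactly_at_threshold_excluded(self):
        sig = eld.significant_pairs(self._table([0.05]))
        assert len(sig) == 0  # single test: q = p = 0.05, strict <

    def test_q_below_threshold_included(self):
        sig = eld.significant_pairs(self._table([0.049]))
        assert len(sig) == 1

    def test_empty_table_passes_through(self):
        sig = eld.significant_pairs(self._table([])[0:0])
        assert len(sig) == 0 and "q_ld" in sig.columns


class TestGeneSetGraph:
    def test_empty_pairs_empty_graph(self):
        sig = pd.DataFrame(columns=["variant_a", "variant_b", "q_ld"])
        g = eld.build_adaptation_gene_set(sig, {}, nx.Graph())
        assert g.number_of_nodes() == 0

    def test_parallel_ld_and_ppi_edges(self):
        sig = pd.DataFrame({"variant_a": ["a"], "variant_b": ["b"],
                            "q_ld": [0.01]})
        ppi = nx.Graph([("G1", "G2")])
        g = eld.build_adaptation_gene_set(sig, {"a": {"G1"}, "b": {"G2"}},
                                          ppi, gene_p={"G1": 0.001})
        assert g.number_of_nodes() == 2
        evidences = sorted(d["evidence"] for _, _, d in g.edges(data=True))
        assert evidences == ["ld", "ppi"]
        assert g.nodes["G1"]["p_gene"] == 0.001
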