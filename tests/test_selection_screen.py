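import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from polyadapt import selection_screen as sel
from polyadapt import synthetic_data as syn
from polyadapt.io_formats import VariantRecord


def brute_force_ehh(hap, core, target):
    """All-pairs identity count over the span (independent oracle)."""
    lo, hi = sorted((core, target))
    n = hap.shape[0]
    same = sum(np.array_equal(hap[i, lo:hi + 1], hap[j, lo:hi + 1])
               for i, j in itertools.combinations(range(n), 2))
    return same / (n * (n - 1) / 2)


class TestEhh:
    def test_identical_carriers_give_one(self):
        hap = np.tile([0, 1, 1, 0], (5, 1))
        assert sel.ehh(hap, 1, 3) == 1.0

    def test_target_equals_core_is_one(self):
        hap = np.array([[1, 0], [1, 1], [1, 0]])
        assert sel.ehh(hap, 0, 0) == 1.0

    def test_four_carriers_two_sites(self):
        # strings over the span: 00, 00, 01, 10 -> one identical pair of six
        hap = np.array([[0, 0], [0, 0], [0, 1], [1, 0]])
        assert sel.ehh(hap, 0, 1) == pytest.approx(1 / 6)

    def test_single_carrier_errors(self):
        with pytest.raises(ValueError):
            sel.ehh(np.array([[1, 0]]), 0, 1)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(2, 12)
            m = rng.integers(2, 15)
            hap = rng.integers(0, 2, size=(n, m))
            core = int(rng.integers(0, m))
            target = int(rng.integers(0, m))
            assert sel.ehh(hap, core, target) == pytest.approx(
                brute_force_ehh(hap, core, target), abs=1e-12)

    @given(hnp.arrays(np.int8, st.tuples(st.integers(2, 10),
                                         st.integers(2, 12)),
                      elements=st.integers(0, 1)))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_any_panel_matches_brute_force(self, hap):
        m = hap.shape[1]
        assert sel.ehh(hap, 0, m - 1) == pytest.approx(
            brute_force_ehh(hap, 0, m - 1), abs=1e-12)

    def test_curve_non_increasing(self, rng):
        for _ in range(20):
            hap = rng.integers(0, 2, size=(8, 30))
            pos = np.arange(30) * 1000
            curve, _ = sel._ehh_curve_one_side(hap, pos, 0, +1, cutoff=0.0)
            vals = [e for _, e in curve]
            assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestIhh:
    def test_hand_trapezoid_with_truncation(self):
        # (1+0.5)/2*1000 + (0.5+0.04)/2*1000 = 750 + 270
        curve = [(0, 1.0), (1000, 0.5), (2000, 0.04), (3000, 0.01)]
        area, edge = sel.ihh([curve], cutoff=0.05)
        assert area == pytest.approx(1020.0)
        assert not edge

    def test_plateau_then_zero(self):
        # EHH = 1 over [0, D], then 0 at the next marker: D + 0.5 * gap
        curve = [(0, 1.0), (4000, 1.0), (4500, 0.0)]
        area, _ = sel.ihh([curve], cutoff=0.05)
        assert area == pytest.approx(4000 + 0.5 * 500)

    def test_empty_far_side_sets_edge_flag(self):
        area, edge = sel.ihh([[(0, 1.0), (100, 0.01)], []], cutoff=0.05)
        assert edge

    def test_never_reaching_cutoff_sets_edge_flag(self):
        _, edge = sel.ihh([[(0, 1.0), (100, 0.8)]], cutoff=0.05)
        assert edge

    def test_bad_curve_start_rejected(self):
        with pytest.raises(ValueError):
            sel.ihh([[(0, 0.9), (10, 0.5)]])


class TestStandardize:
    def _frame(self, freqs, raw):
        import pandas as pd

        return pd.DataFrame({"derived_freq": freqs,
                             "ihs_unstandardized": raw})

    def test_single_bin_hand_case(self):
        df = self._frame([0.31, 0.32, 0.33], [0.6, 0.8, 1.0])
        out = sel.ihs_standardize(df, n_bins=20)
        assert list(out["ihs"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_bin_flagged_not_infinite(self):
        df = self._frame([0.31, 0.32, 0.33], [0.7, 0.7, 0.7])
        out = sel.ihs_standardize(df, n_bins=20)
        assert out["ihs"].isna().all()

    def test_sparse_bin_flagged(self):
        df = self._frame([0.1, 0.12, 0.14, 0.9], [0.1, 0.5, 0.9, 2.0])
        out = sel.ihs_standardize(df, n_bins=20)
        assert np.isnan(out["ihs"].iloc[3])

    def test_bins_standardized_independently(self):
        df = self._frame([0.11, 0.12, 0.13, 0.81, 0.82, 0.83],
                         [1.0, 2.0, 3.0, -5.0, 0.0, 5.0])
        out = sel.ihs_standardize(df, n_bins=10)
        for lo, hi in ((0, 3), (3, 6)):
            vals = out["ihs"].iloc[lo:hi]
            assert vals.mean() == pytest.approx(0.0, abs=1e-12)
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestFilter:
    def _v(self, vid, ihs):
        return VariantRecord(vid, "1", 100, p_gwas=0.5, ihs=ihs)

    def test_threshold_is_strict_and_absolute(self):
        vs = [self._v("at", 1.5), self._v("neg", -1.6), self._v("pos", 1.51),
              self._v("none", None)]
        kept = sel.filter_by_ihs(vs, threshold=1.5)
        assert [v.variant_id for v in kept] == ["neg", "pos"]

    def test_all_missing_gives_empty(self):
        assert sel.filter_by_ihs([self._v("a", None)]) == []

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            sel.filter_by_ihs([], threshold=0.0)


class TestSweepSignal:
    def test_no_recombination_no_mutation_carriers_identical(self):
        cfg = syn.SimulationConfig(
            seed=3, n_samples=30, n_chrom=1, variants_per_chrom=40,
            n_genes=2,
            sweeps=(syn.SweepConfig("rs1_20", derived_freq=0.5,
                                    recomb_rate_per_bp=1e-300,
                                    mutation_rate_per_site=0.0),))
        panel = syn.simulate_panel(cfg)
        core = 19
        carriers = panel.haplotypes[panel.haplotypes[:, core] == 1]
        assert (carriers == carriers[0]).all()
        assert sel.ehh(carriers, core, 0) == 1.0
        assert sel.ehh(carriers, core, 39) == 1.0

    def test_sweep_core_ihs_exceeds_background(self):
        # |iHS| at the planted core above the 95th background percentile in
        # a clear majority of seeds (stochastic, matched to the sweep model)
        wins = 0
        for seed in range(10):
            cfg = syn.SimulationConfig(
                seed=seed, n_samples=100, n_chrom=2, variants_per_chrom=150,
                n_genes=4,
                sweeps=(syn.SweepConfig("rs1_75", derived_freq=0.5,
                                        recomb_rate_per_bp=1e-6),))
            panel = syn.simulate_panel(cfg)
            scores = sel.ihs_scores(panel).set_index("variant_id")
            if "rs1_75" not in scores.index:
                continue
            core = abs(scores.loc["rs1_75", "ihs"])
            bg = scores.drop(index="rs1_75")["ihs"].abs().dropna()
            if core > np.percentile(bg, 95):
                wins += 1
        assert wins >= 7

    def test_attach_by_position(self):
        import pandas as pd

        vs = [VariantRecord("other_name", "1", 500, p_gwas=0.5)]
        table = pd.DataFrame({"variant_id": ["x"], "chrom": ["1"],
                              "pos": [500], "ihs": [2.2]})
        out = sel.attach_ihs(vs, table, match_by="position")
        assert out[0].ihs == 2.2
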