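"""Foreground design, BH-FDR, chi-squared tests and the run comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ploidymix.selection import (
    LocusSelectionRecord,
    bh_fdr,
    build_foreground_sets,
    chi_square_test,
    compare_selection,
    read_selection_table,
    write_selection_table,
)
from ploidymix.simulate import PvalSimConfig, simulate_pvalue_table


def bh_bruteforce(ps):
    """Independent step-up oracle: p_(i) * n / i with running minimum."""
    n = len(ps)
    order = np.argsort(ps, kind="stable")
    adj = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * n / rank)
        adj[i] = prev
    return adj


class TestForegroundDesign:
    def test_exact_partition(self):
        pool = [f"d{i}" for i in range(168)]
        design = build_foreground_sets(pool, n_sets=6, size_range=(27, 28), seed=1)
        assert [len(s) for s in design.diploid_sets] == [28] * 6
        assert design.n_reused == 0
        union = set().union(*design.diploid_sets)
        assert union == set(pool)

    def test_pool_shortfall_forces_exactly_two_reuses(self):
        # 6 * 27 = 162 > 160, so exactly 2 taxa must appear twice
        pool = [f"d{i}" for i in range(160)]
        design = build_foreground_sets(pool, n_sets=6, size_range=(27, 27), seed=2)
        assert [len(s) for s in design.diploid_sets] == [27] * 6
        assert design.n_reused == 2
        flat = [t for s in design.diploid_sets for t in s]
        assert len(flat) - len(set(flat)) == 2
        for s in design.diploid_sets:  # no repeats within a set
            assert len(s) == len(set(s))

    def test_tiny_pool_rejected(self):
        with pytest.raises(ValueError):
            build_foreground_sets([f"d{i}" for i in range(10)])

    def test_seed_determinism(self):
        pool = [f"d{i}" for i in range(170)]
        a = build_foreground_sets(pool, seed=9)
        b = build_foreground_sets(pool, seed=9)
        assert a.diploid_sets == b.diploid_sets


class TestBhFdr:
    def test_worked_example(self):
        res = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert [r.p_adj for r in res] == pytest.approx([0.04, 0.04, 0.04, 0.5])
        assert sum(r.selected for r in res) == 3

    def test_all_ones_select_nothing(self):
        assert not any(r.selected for r in bh_fdr([1.0] * 7))

    def test_empty_input(self):
        assert bh_fdr([]) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_stepup_oracle(self, ps, _seed):
        res = bh_fdr(ps)
        assert np.allclose([r.p_adj for r in res], bh_bruteforce(ps), atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ps = rng.random(rng.integers(1, 40))
            res = bh_fdr(list(ps))
            adj = np.array([r.p_adj for r in res])
            assert np.all(adj >= ps - 1e-12)
            order = np.argsort(ps, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-12)


class TestChiSquare:
    def test_hand_computed_table(self):
        # expected counts [[20,80],[20,80]] -> chi2 = 12.5, df = 1
        res = chi_square_test([[30, 70], [10, 90]])
        assert res.chi2 == pytest.approx(12.5, abs=1e-10)
        assert res.df == 1

    def test_proportional_rows_give_zero(self):
        assert chi_square_test([[10, 20], [20, 40]]).chi2 == pytest.approx(0.0)

    def test_df_formula_for_2x4(self):
        res = chi_square_test([[5, 6, 7, 8], [8, 7, 6, 5]])
        assert res.df == 3

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = rng.integers(1, 60, size=(rng.integers(2, 4), rng.integers(2, 5)))
            res = chi_square_test(t)
            expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
            chi2 = ((t - expected) ** 2 / expected).sum()
            assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_degenerate_and_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            chi_square_test([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            chi_square_test([[1, 2]])


class TestCompareSelection:
    def make_records(self, seed, poly_frac=0.3, dip_frac=0.3):
        cfg = PvalSimConfig(
            runs=("polyploid", "diploid_1", "diploid_2"),
            signal_fraction={
                "polyploid": poly_frac,
                "diploid_1": dip_frac,
                "diploid_2": dip_frac,
            },
            seed=seed,
        )
        return simulate_pvalue_table(cfg)

    def test_counts_conservation_and_percentages(self):
        summary = compare_selection(self.make_records(3), "polyploid")
        counts = summary.counts
        expected_totals = {
            "defence_chemistry": 113,
            "single_copy": 1044,
            "differentially_expressed": 109,
            "miscellaneous": 54,
        }
        for (run, ann), sub in counts.groupby(["run_id", "annotation"]):
            assert int(sub["n_total"].iloc[0]) == expected_totals[ann]
        assert np.allclose(
            counts["pct_selected"],
            100.0 * counts["n_selected"] / counts["n_total"],
        )

    def test_missing_polyploid_run_rejected(self):
        records = [
            LocusSelectionRecord("l1", "single_copy", "diploid_1", 0.5),
            LocusSelectionRecord("l2", "single_copy", "diploid_2", 0.5),
        ]
        with pytest.raises(ValueError, match="polyploid"):
            compare_selection(records, "polyploid")

    def test_equal_selected_fractions_give_zero_chi2(self):
        # identical counts in both runs -> independence -> chi2 == 0
        res = chi_square_test([[40, 73], [40, 73]])
        assert res.chi2 == pytest.approx(0.0)

    def test_planted_enrichment_power(self):
        """Detection frequency of a planted 0.65 vs 0.50 selected-fraction
        difference at n = 113 matches the Monte-Carlo power oracle (0.634,
        frozen with a 3-se allowance over 100 replicates)."""
        rng = np.random.default_rng(42)
        n = 113
        hits = 0
        for _ in range(100):
            a = rng.binomial(n, 0.65)
            b = rng.binomial(n, 0.50)
            res = chi_square_test([[a, n - a], [b, n - b]])
            hits += res.p < 0.05
        assert hits >= 50

    def test_ploidy_tests_emitted_per_annotation_and_run(self):
        summary = compare_selection(self.make_records(4), "polyploid")
        keys = set(summary.ploidy_tests)
        assert ("defence_chemistry", "diploid_1") in keys
        assert ("single_copy", "diploid_2") in keys
        for res in summary.ploidy_tests.values():
            assert res.df == 1 and res.chi2 >= 0

    def test_table_roundtrip(self, tmp_path):
        records = self.make_records(5)[:200]
        p = tmp_path / "sel.tsv"
        write_selection_table(records, p, comment="test")
        back = read_selection_table(p)
        assert back == records
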