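import itertools
import logging

import numpy as np
import pytest

import slimpact as sp
from slimpact.enrichment_stats import ContingencyTable

from .oracles import (
    fisher_2x2_oracle,
    fisher_rxc_oracle,
    ranksum_exact_oracle,
    ranksum_permutation_oracle,
)


class TestFisher2x2:
    def test_balanced_table_is_null(self):
        assert sp.fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_small_table_against_enumeration(self):
        assert sp.fisher_exact([[3, 1], [1, 3]]) == pytest.approx(
            fisher_2x2_oracle([[3, 1], [1, 3]]), abs=1e-12
        )

    def test_all_tables_total_up_to_20_match_oracle(self):
        for n in range(1, 21):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        table = [[a, b], [c, d]]
                        if min(a + b, c + d) == 0 or min(a + c, b + d) == 0:
                            continue
                        assert sp.fisher_exact(table) == pytest.approx(
                            fisher_2x2_oracle(table), abs=1e-12
                        ), table

    def test_degenerate_margin_gives_one(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert sp.fisher_exact([[0, 0], [3, 4]]) == 1.0
        assert "degenerate" in caplog.text


class TestFisherRxc:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ([[52, 100, 4], [37, 27, 3]], 0.003),
            ([[200, 285, 13], [52, 100, 4]], 0.299),
            ([[37, 27, 3], [200, 285, 13]], 0.023),
        ],
    )
    def test_2x3_reproduces_printed_category_tests(self, table, printed):
        assert round(sp.fisher_exact(table), 3) == printed

    def test_small_rxc_against_fraction_oracle(self, rng):
        for _ in range(25):
            r, c = int(rng.integers(2, 4)), int(rng.integers(2, 4))
            table = rng.integers(0, 6, size=(r, c))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            assert sp.fisher_exact(table) == pytest.approx(
                fisher_rxc_oracle(table), abs=1e-9
            ), table

    def test_invariant_under_row_and_column_permutation(self, rng):
        for _ in range(10):
            table = rng.integers(0, 8, size=(2, 3))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            p = sp.fisher_exact(table)
            for rows in itertools.permutations(range(2)):
                for cols in itertools.permutations(range(3)):
                    assert sp.fisher_exact(table[np.ix_(rows, cols)]) == pytest.approx(
                        p, rel=1e-9
                    )

    def test_monte_carlo_fallback_agrees_with_enumeration(self):
        from slimpact.enrichment_stats import _fisher_rxc_monte_carlo

        table = np.array([[52, 100, 4], [37, 27, 3]])
        p_mc = _fisher_rxc_monte_carlo(table, np.random.default_rng(1))
        assert p_mc == pytest.approx(sp.fisher_exact(table), abs=0.005)

    def test_p_always_in_unit_interval(self, rng):
        for _ in range(50):
            table = rng.integers(0, 12, size=(2, 2))
            p = sp.fisher_exact(table)
            assert 0.0 < p <= 1.0 + 1e-12


class TestOddsRatio:
    def test_cross_product(self):
        assert sp.odds_ratio([[6, 2], [3, 9]]) == pytest.approx(9.0)

    def test_haldane_correction_on_zero_cell(self):
        assert sp.odds_ratio([[5, 0], [2, 8]]) == pytest.approx(
            (5.5 * 8.5) / (0.5 * 2.5)
        )

    def test_non_2x2_is_error(self):
        with pytest.raises(ValueError):
            sp.odds_ratio([[1, 2, 3], [4, 5, 6]])


class TestSiteOverlapEnrichment:
    def test_planted_enrichment_detected_in_disordered_region(self, small_study):
        sites = {k: sp.collapse_sites(v) for k, v in small_study.mutations.items()}
        res = sp.site_overlap_enrichment(
            sites["disease"], sites["neutral"],
            small_study.manifest, small_study.tracks,
            labels=("disease", "neutral"),
        )["disordered"]
        assert res.testable and res.p_value < 0.01
        assert res.odds_ratio > 1.0

    def test_no_overlap_gives_p_one(self, small_study):
        sites = {k: sp.collapse_sites(v) for k, v in small_study.mutations.items()}
        far_instances = [
            sp.MotifInstance(acc, "T", 1, 1, p.sequence[0], mean_disorder=0.9,
                             mean_rlc=1.0)
            for acc, p in list(small_study.proteome.items())[:5]
        ]
        shifted = {
            k: {s for s in v if s.position > 1} for k, v in sites.items()
        }
        res = sp.site_overlap_enrichment(
            shifted["disease"], shifted["neutral"], far_instances,
            small_study.tracks,
        )
        for r in res.values():
            assert r.table.to_array()[:, 0].sum() == 0
            assert r.p_value == 1.0

    def test_row_totals_cover_only_shared_motif_proteins(self, small_study):
        sites = {k: sp.collapse_sites(v) for k, v in small_study.mutations.items()}
        res = sp.site_overlap_enrichment(
            sites["disease"], sites["neutral"],
            small_study.manifest, small_study.tracks,
        )
        motif_prots = {i.accession for i in small_study.manifest}
        shared = (
            {s.accession for s in sites["disease"]}
            & {s.accession for s in sites["neutral"]}
            & motif_prots
        )
        n_counted = sum(
            r.table.to_array().sum() for r in res.values()
        )
        n_expected = sum(
            1
            for k in ("disease", "neutral")
            for s in sites[k]
            if s.accession in shared
        )
        assert n_counted == n_expected


class TestRlcBinnedEnrichment:
    def test_pooled_within_counts_reproduce_unbinned_overlap(self, small_study):
        """Summing the within-motif column over all RLC bins conserves the
        unbinned count of disordered sites overlapping any instance."""
        sites = {k: sp.collapse_sites(v) for k, v in small_study.mutations.items()}
        results = sp.rlc_binned_enrichment(
            small_study.manifest, sites["disease"], sites["neutral"],
            small_study.tracks,
        )
        pooled_within = sum(r.table.to_array()[:, 0] for r in results)
        covered = {
            (i.accession, p) for i in small_study.manifest for p in i.span
        }
        expected = np.zeros(2, dtype=int)
        outside = np.zeros(2, dtype=int)
        for row, name in enumerate(("disease", "neutral")):
            for s in sites[name]:
                track = small_study.tracks[s.accession]
                if track.disorder[s.position - 1] <= 0.5:
                    continue
                if (s.accession, s.position) in covered:
                    expected[row] += 1
                else:
                    outside[row] += 1
        np.testing.assert_array_equal(pooled_within, expected)
        for r in results:  # the outside pool is common to every bin
            np.testing.assert_array_equal(r.table.to_array()[:, 1], outside)

    def test_signal_sits_in_high_rlc_bins(self, small_study):
        """Planted motifs carry RLC > 0.5, so only bins above 0.5 can show
        within-motif enrichment; lower bins hold no motif residues."""
        sites = {k: sp.collapse_sites(v) for k, v in small_study.mutations.items()}
        results = sp.rlc_binned_enrichment(
            small_study.manifest, sites["disease"], sites["neutral"],
            small_study.tracks,
        )
        significant = [r for r in results if r.testable and r.p_value < 0.01]
        assert significant, "expected at least one enriched RLC bin"
        for r in significant:
            low_edge = float(r.stratum.split("[")[1].split(",")[0])
            assert low_edge >= 0.5

    def test_empty_bins_flagged_untestable(self, small_study):
        sites = {k: sp.collapse_sites(v) for k, v in small_study.mutations.items()}
        results = sp.rlc_binned_enrichment(
            [], set(), sites["neutral"], small_study.tracks
        )
        assert all(not r.testable for r in results)


class TestPropertyTests:
    def _mat(self, pairs):
        muts = [sp.MutationRecord("P", 1, wt, mut, "d") for wt, mut in pairs]
        return sp.transition_matrix(muts, "charge")

    def test_identical_matrices_null(self):
        m = self._mat([("R", "A"), ("D", "E")])
        assert sp.property_change_test(m, m) == pytest.approx(1.0)

    def test_extreme_separation_matches_oracle(self):
        a = self._mat([("R", "A")] * 10)   # 10 changes, 0 no-change
        b = self._mat([("R", "K")] * 10)   # 0 changes, 10 no-change
        assert sp.property_change_test(a, b) == pytest.approx(
            fisher_2x2_oracle([[10, 0], [0, 10]]), abs=1e-12
        )

    def test_reconstructed_hydropathy_comparison(self):
        """Change fractions 51/67 vs 83/156 on the hydropathy scheme: the
        exact test agrees with the integer-weight oracle and shows the
        disease-like excess of property-changing substitutions."""
        table = [[51, 16], [83, 73]]
        p = sp.fisher_exact(table)
        assert p == pytest.approx(fisher_2x2_oracle(table), abs=1e-12)
        assert p < 0.05

    def test_transition_specific_identical_rows(self):
        m = self._mat([("R", "A"), ("R", "K")])
        assert sp.transition_specific_test(
            m, m, "positively charged", "uncharged"
        ) == pytest.approx(1.0)

    def test_transition_specific_matches_oracle(self):
        a = self._mat([("R", "A")] * 8 + [("R", "K")] * 2)
        b = self._mat([("R", "A")] * 1 + [("R", "K")] * 9)
        p = sp.transition_specific_test(a, b, "positively charged", "uncharged")
        assert p == pytest.approx(fisher_2x2_oracle([[8, 2], [1, 9]]), abs=1e-12)


class TestWilcoxonRankSum:
    def test_identical_samples(self):
        assert sp.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_tiny_exact_case(self):
        assert sp.wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_exact_agrees_with_enumeration(self, rng):
        for _ in range(10):
            x = rng.permutation(40)[: int(rng.integers(3, 8))].tolist()
            y = [v for v in rng.permutation(40)[:8].tolist() if v not in x][:6]
            assert sp.wilcoxon_rank_sum(x, y) == pytest.approx(
                ranksum_exact_oracle(x, y), abs=1e-9
            )

    def test_large_sample_agrees_with_permutation_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=40).round(1)
        y = rng.normal(0.6, 1.0, size=35).round(1)
        p = sp.wilcoxon_rank_sum(x, y)
        p_perm = ranksum_permutation_oracle(x, y, n_draws=20_000, seed=3)
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            sp.wilcoxon_rank_sum([], [1.0])


def test_contingency_table_rejects_negative_counts():
    with pytest.raises(ValueError):
        ContingencyTable.from_array([[1, -1], [0, 2]])
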