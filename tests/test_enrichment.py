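"""Permutation enrichment: counting rule, matched sampling, empirical p,
SMD, Fisher combination — all against hand values or brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from enzfam.enrichment import (
    MatchingError,
    cgc_enrichment,
    count_recurrently_mutated_genes,
    fisher_combine,
    permutation_enrichment,
    result_from_null,
    sample_matched_gene_set,
    summarize_family,
)
from enzfam.io import GeneModel

from conftest import make_events


class TestRecurrenceCounting:
    def test_three_hits_in_one_patient_not_counted(self, tiny_universe):
        events = make_events([("P1", "G0", "missense")] * 3)
        assert count_recurrently_mutated_genes(events, tiny_universe, {"G0"}) == 0

    def test_two_patients_different_deleterious_classes_counted(self, tiny_universe):
        events = make_events([("P1", "G0", "missense"), ("P2", "G0", "splice_site")])
        assert count_recurrently_mutated_genes(events, tiny_universe, {"G0"}) == 1

    def test_silent_events_never_counted(self, tiny_universe):
        events = make_events([("P1", "G0", "silent"), ("P2", "G0", "silent")])
        assert count_recurrently_mutated_genes(events, tiny_universe, {"G0"}) == 0

    def test_foreign_gene_in_set_rejected(self, tiny_universe):
        with pytest.raises(ValueError, match="GX"):
            count_recurrently_mutated_genes([], tiny_universe, {"GX"})


class TestMatchedSampling:
    def test_accepted_totals_within_five_percent(self, tiny_universe, rng):
        ref = {"G0", "G1", "G2"}  # total 3100 bp
        lengths = {g.gene_id: g.length_bp for g in tiny_universe}
        target = sum(lengths[g] for g in ref)
        for _ in range(50):
            picked = sample_matched_gene_set(tiny_universe, ref, rng)
            total = sum(lengths[g] for g in picked)
            assert len(picked) == 3
            assert 0.95 * target <= total <= 1.05 * target

    def test_reference_equal_to_universe_returns_universe(self, tiny_universe, rng):
        ref = {g.gene_id for g in tiny_universe}
        assert sample_matched_gene_set(tiny_universe, ref, rng) == ref

    def test_attempt_budget_exhaustion_errors_not_relaxes(self):
        # one tiny reference gene among huge genes: almost every draw misses
        # the ±5% window, so a small budget must error, never widen the band
        universe = [GeneModel("A", "chr1", 0, 100)] + [
            GeneModel(f"B{i}", "chr1", 200 + i * 20_000, 200 + i * 20_000 + 10_000)
            for i in range(200)
        ]
        rng = np.random.default_rng(0)
        with pytest.raises(MatchingError, match="coverage"):
            sample_matched_gene_set(universe, {"A"}, rng, max_attempts=10)


class TestEmpiricalStatistics:
    def test_smd_hand_value(self):
        res = result_from_null(10, [4, 6, 5, 5])
        assert res.smd == pytest.approx((10 - 5) / 0.8165, abs=1e-3)

    def test_p_emp_add_one_rule(self):
        res = result_from_null(10, [11, 4, 5, 6])
        assert res.p_emp == pytest.approx(2 / 5)

    def test_observed_equal_to_all_null_gives_zero_smd_and_p_one(self):
        res = result_from_null(5, [5, 5, 5, 5])
        assert res.smd == 0.0
        assert res.p_emp == 1.0
        assert not res.smd_undefined

    def test_degenerate_null_flagged_not_fabricated(self):
        res = result_from_null(9, [5, 5, 5, 5])
        assert res.smd_undefined
        assert math.isnan(res.smd)

    def test_p_emp_floor_respected(self, tiny_universe, rng):
        events = make_events(
            [(f"P{i}", g, "missense") for g in ("G0", "G1", "G2") for i in range(3)]
        )
        res = permutation_enrichment(
            events, tiny_universe, {"G0", "G1", "G2"}, rng, n_perm=200
        )
        assert res.p_emp >= 1 / 201

    def test_exactness_against_enumeration(self, rng):
        """10,000 draws reproduce the exhaustive-subset probability (±0.02)."""
        lengths = [1000, 1100, 1200, 900, 1000, 1050, 5000, 5200, 980, 1020]
        universe = []
        pos = 0
        for i, ln in enumerate(lengths):
            universe.append(GeneModel(f"G{i}", "chr1", pos, pos + ln))
            pos += ln + 100
        # recurrent genes: G0, G1, G6
        events = make_events(
            [(p, g, "missense") for g in ("G0", "G1", "G6") for p in ("P1", "P2")]
        )
        gene_set = {"G0", "G1", "G2"}
        target = sum(lengths[:3])
        recurrent = {"G0", "G1", "G6"}
        observed = len(gene_set & recurrent)
        admissible = [
            s for s in itertools.combinations(range(10), 3)
            if 0.95 * target <= sum(lengths[i] for i in s) <= 1.05 * target
        ]
        exact = sum(
            1 for s in admissible
            if len({f"G{i}" for i in s} & recurrent) >= observed
        ) / len(admissible)
        res = permutation_enrichment(events, universe, gene_set, rng, n_perm=10_000)
        assert res.p_emp == pytest.approx(exact, abs=0.02)


class TestFisherCombination:
    def test_single_p_identity(self):
        _, p = fisher_combine([0.05])
        assert p == pytest.approx(0.05, abs=1e-12)

    def test_closed_form_hand_value(self):
        x, p = fisher_combine([0.1, 0.1])
        assert x == pytest.approx(9.2103, abs=1e-4)
        assert p == pytest.approx(0.056052, abs=1e-6)

    def test_all_ones_combine_to_one(self):
        x, p = fisher_combine([1.0, 1.0, 1.0])
        assert x == 0.0
        assert p == 1.0

    def test_matches_even_df_series_closed_form(self, rng):
        """chi2.sf agrees with exp(-X/2) Σ_{j<k} (X/2)^j / j! to 1e-10."""
        for _ in range(200):
            k = int(rng.integers(1, 8))
            ps = rng.uniform(1e-6, 1.0, size=k)
            x, p = fisher_combine(ps)
            half = x / 2
            series = math.exp(-half) * sum(half**j / math.factorial(j) for j in range(k))
            assert p == pytest.approx(series, abs=1e-10)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.5, 0.0])


class TestFamilySummary:
    def test_single_type_collapses_to_that_result(self):
        res = result_from_null(10, [4, 6, 5, 5], family="helicase", cancer_type="BRCA")
        summ = summarize_family([res])
        assert summ.mean_smd == res.smd
        assert summ.smd_p5 == summ.smd_p95 == res.smd
        assert summ.combined_p == pytest.approx(res.p_emp)

    def test_percentiles_linear_interpolation(self):
        results = [
            result_from_null(obs, [0, 1, 2, 1], family="f")
            for obs in (1, 2, 3, 4, 5)
        ]
        smds = [r.smd for r in results]
        summ = summarize_family(results)
        assert summ.mean_smd == pytest.approx(np.mean(smds))
        assert summ.smd_p5 == pytest.approx(np.percentile(smds, 5))
        assert summ.smd_p95 == pytest.approx(np.percentile(smds, 95))

    def test_all_p_one_combined_is_one(self):
        results = [result_from_null(0, [1, 2, 3, 2]) for _ in range(3)]
        assert summarize_family(results).combined_p == 1.0


class TestCgcEnrichment:
    @staticmethod
    def _universe(a, b, c, d):
        """Build a universe realizing 2×2 counts [[a,b],[c,d]]."""
        genes, fam, cgc = [], set(), set()
        idx = 0
        for n, in_fam, in_cgc in ((a, 1, 1), (b, 1, 0), (c, 0, 1), (d, 0, 0)):
            for _ in range(n):
                gid = f"G{idx}"
                genes.append(GeneModel(gid, "chr1", idx * 10, idx * 10 + 5))
                if in_fam:
                    fam.add(gid)
                if in_cgc:
                    cgc.add(gid)
                idx += 1
        return genes, fam, cgc

    def test_odds_ratio_hand_value(self):
        genes, fam, cgc = self._universe(10, 5, 5, 80)
        odds, p = cgc_enrichment(fam, cgc, genes)
        assert odds == pytest.approx(32.0)
        _, p_ref = stats.fisher_exact([[10, 5], [5, 80]])
        assert p == pytest.approx(p_ref)

    def test_independence_table(self):
        genes, fam, cgc = self._universe(25, 25, 25, 25)
        odds, p = cgc_enrichment(fam, cgc, genes)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_depletion_direction_preserved(self):
        genes, fam, cgc = self._universe(0, 10, 40, 10)
        odds, _ = cgc_enrichment(fam, cgc, genes)
        assert odds < 1
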