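"""Tests for the statistics layer: correlations, resampling, enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicesurvey.profile_analysis import (
    compare_gene_sets,
    compare_intron_lengths,
    correlate_counts,
    divergence_frequency_correlation,
    long_intron_enrichment,
    noncanonical_by_intron_count,
    profile_similarity_matrix,
)
from splicesurvey.splice_sites import Intron, SpeciesProfile

from conftest import spearman_oracle


def profile(counts, species="sp", ambiguous=0):
    return SpeciesProfile(
        species=species,
        counts=dict(counts),
        ambiguous_masked=ambiguous,
        total_introns=sum(counts.values()) + ambiguous,
    )


class TestSpearmanAgainstOracle:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=4, max_size=50),
        st.data(),
    )
    def test_correlate_counts_matches_brute_force(self, x, data):
        y = data.draw(
            st.lists(
                st.integers(min_value=0, max_value=20),
                min_size=len(x),
                max_size=len(x),
            )
        )
        if np.std(x) == 0 or np.std(y) == 0:
            return  # undefined correlation; scipy returns nan
        result = correlate_counts(x, y)
        assert result.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_trivial_monotone(self):
        assert correlate_counts([1, 2, 3], [2, 4, 6]).rho == pytest.approx(1.0)
        assert correlate_counts([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            correlate_counts([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            correlate_counts([1, 2], [1, 2])


class TestDivergenceFrequency:
    def test_perfect_monotone_restricted(self):
        # distances 1,2,3 with counts 30,20,10: all other combos count 0, so
        # restrict to observed combos via a small custom check
        counts = {"GAAG": 30, "GAAA": 20, "AAAA": 10}  # d = 1? no: craft below
        # use combos with known distances to GTAG: GTAA d1, GTCC d2, CCCC d4
        counts = {"GTAA": 30, "GTCC": 20, "CCCC": 10}
        prof = profile(counts)
        x = [1, 2, 4]
        y = [30, 20, 10]
        assert spearman_oracle(x, y) == pytest.approx(-1.0)
        result = divergence_frequency_correlation(prof)
        # full-256 version includes zero-count combos; verify against oracle
        from splicesurvey.splice_sites import ALL_COMBOS, CANONICAL, hamming_distance

        dist = [hamming_distance(c, CANONICAL) for c in ALL_COMBOS]
        cnt = [counts.get(c, 0) for c in ALL_COMBOS]
        assert result.rho == pytest.approx(spearman_oracle(dist, cnt), abs=1e-12)
        assert result.n == 256

    def test_pooling_sums_counts(self):
        p1 = profile({"GTAG": 10, "GCAG": 1})
        p2 = profile({"GTAG": 5, "ATAC": 2})
        pooled = divergence_frequency_correlation([p1, p2])
        manual = profile({"GTAG": 15, "GCAG": 1, "ATAC": 2})
        assert pooled.rho == pytest.approx(
            divergence_frequency_correlation(manual).rho
        )

    def test_scale_invariance(self):
        p = profile({"GTAG": 100, "GCAG": 10, "CAGG": 1})
        scaled = profile({"GTAG": 700, "GCAG": 70, "CAGG": 7})
        assert divergence_frequency_correlation(p).rho == pytest.approx(
            divergence_frequency_correlation(scaled).rho, abs=1e-12
        )

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            divergence_frequency_correlation(profile({}))


class TestSimilarityMatrix:
    def test_identical_profiles_rho_one(self):
        p = profile({"GTAG": 10, "GCAG": 3, "CAGG": 1})
        matrix = profile_similarity_matrix([p, p])
        assert matrix.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        from splicesurvey.splice_sites import ALL_COMBOS

        profiles = [
            profile(
                {c: int(n) for c, n in zip(ALL_COMBOS, rng.integers(0, 50, 256))},
                species=f"s{i}",
            )
            for i in range(3)
        ]
        matrix = profile_similarity_matrix(profiles)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 1.0)

    def test_value_matches_oracle(self):
        p1 = profile({"GTAG": 9, "GCAG": 4, "CAGG": 2})
        p2 = profile({"GTAG": 20, "GCAG": 1, "ATAC": 3})
        matrix = profile_similarity_matrix([p1, p2])
        assert matrix.iloc[0, 1] == pytest.approx(
            spearman_oracle(p1.vector(), p2.vector()), abs=1e-12
        )

    def test_zero_variance_reported_missing(self):
        flat = profile({})  # all-zero counts: no variance
        p = profile({"GTAG": 5, "GCAG": 1})
        matrix = profile_similarity_matrix([flat, p])
        assert np.isnan(matrix.iloc[0, 1])
        assert matrix.iloc[0, 0] == 1.0


class TestCompareIntronLengths:
    def test_null_behaviour(self):
        rng = np.random.default_rng(42)
        background = rng.lognormal(5.3, 0.6, size=600)
        focal = rng.choice(background, size=60, replace=False)
        result = compare_intron_lengths(focal, background, reps=100, seed=1)
        assert result.median_p > 0.05
        assert result.reps == 100

    def test_power_with_shift(self):
        rng = np.random.default_rng(42)
        background = rng.lognormal(5.3, 0.6, size=600)
        focal = rng.choice(background, size=60, replace=False) + 1000
        result = compare_intron_lengths(focal, background, reps=100, seed=1)
        assert result.median_p < 0.01
        assert result.mean_of_mean_differences > 0

    def test_deterministic_given_seed(self):
        background = np.arange(1000.0)
        focal = np.arange(50.0) + 200
        r1 = compare_intron_lengths(focal, background, reps=20, seed=7)
        r2 = compare_intron_lengths(focal, background, reps=20, seed=7)
        assert r1.p_values == r2.p_values
        assert r1.mean_differences == r2.mean_differences

    def test_background_too_small(self):
        with pytest.raises(ValueError):
            compare_intron_lengths([1.0, 2.0], [1.0], reps=10, seed=0)


def intron_with(combo, length, idx=0):
    return Intron("c", 0, length, "+", combo, "t", idx)


class TestLongIntronEnrichment:
    def test_enriched_combo_ranks_first(self):
        introns = (
            [intron_with("AATA", 6000, i) for i in range(2)]
            + [intron_with("CCGC", 6000, i) for i in range(8)]
            + [intron_with("AATA", 100, i) for i in range(1)]
            + [intron_with("CCGC", 100, i) for i in range(999)]
        )
        enrichments, base_table, warning = long_intron_enrichment(introns, 5000)
        assert not warning
        assert enrichments[0].combo == "AATA"
        assert enrichments[0].rank == 1
        # ratio with pseudocounts: ((2+1)/(10+1)) / ((1+1)/(1000+1))
        assert enrichments[0].ratio == pytest.approx((3 / 11) / (2 / 1001))

    def test_ties_break_lexicographically(self):
        introns = [
            intron_with(c, length)
            for c in ("TTCC", "AAGG")
            for length in (6000, 100)
        ]
        enrichments, _, _ = long_intron_enrichment(introns, 5000)
        assert [e.combo for e in enrichments] == ["AAGG", "TTCC"]

    def test_no_long_introns_warns(self):
        enrichments, table, warning = long_intron_enrichment(
            [intron_with("AATA", 100)], 5000
        )
        assert warning and enrichments == [] and table.empty

    def test_only_minor_unambiguous_considered(self):
        introns = [
            intron_with("GTAG", 6000),
            intron_with("GCAG", 6000),
            intron_with("GNAA", 6000),
            intron_with("AATA", 6000),
            intron_with("AATA", 100),
        ]
        enrichments, _, _ = long_intron_enrichment(introns, 5000)
        assert {e.combo for e in enrichments} == {"AATA"}

    def test_base_table_composition(self):
        introns = [intron_with("AATA", 6000), intron_with("AATA", 100)]
        _, table, _ = long_intron_enrichment(introns, 5000)
        row = table.iloc[0]
        assert row["A"] == pytest.approx(0.75)
        assert row["T"] == pytest.approx(0.25)
        assert row["G"] == 0.0


class TestNoncanonicalByIntronCount:
    def test_degenerate_probabilities(self):
        all_false = [(n, False) for n in range(1, 6) for _ in range(20)]
        table = noncanonical_by_intron_count(all_false)
        assert (table["median"] == 0).all()
        all_true = [(n, True) for n in range(1, 6) for _ in range(20)]
        table = noncanonical_by_intron_count(all_true)
        assert (table["median"] == 1).all()

    def test_matches_independence_model(self):
        # per-intron non-canonical probability q: P(gene has one) = 1-(1-q)^n
        q = 0.02
        rng = np.random.default_rng(5)
        entries = []
        for n in range(1, 21):
            hits = rng.random((10_000, n)) < q
            entries.extend((n, bool(h)) for h in hits.any(axis=1))
        table = noncanonical_by_intron_count(entries)
        for _, row in table.iterrows():
            n = int(row["intron_count"])
            expected = 1 - (1 - q) ** n
            se = np.sqrt(expected * (1 - expected) / 10_000)
            assert abs(row["median"] - expected) <= 3 * se

    def test_quartiles_across_species(self):
        summaries = {
            "a": [(1, True)] * 10,
            "b": [(1, False)] * 10,
            "c": [(1, True)] * 5 + [(1, False)] * 5,
        }
        table = noncanonical_by_intron_count(summaries)
        assert table.loc[0, "median"] == pytest.approx(0.5)
        assert table.loc[0, "n_species"] == 3

    def test_rejects_zero_intron_count(self):
        with pytest.raises(ValueError):
            noncanonical_by_intron_count([(0, True)])


class TestCompareGeneSets:
    def test_null_identical_lists(self):
        pairs = [(0.1 + 0.01 * i, 0.1 + 0.01 * i) for i in range(10)]
        result = compare_gene_sets(pairs)
        assert result.p_value > 0.9

    def test_power_with_offset(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0.05, 0.15, size=30)
        pairs = list(zip(base + 0.05, base))
        result = compare_gene_sets(pairs)
        assert result.p_value < 0.05
        assert result.mean_in_set > result.mean_overall

    def test_means_reported(self):
        pairs = [(0.2, 0.1), (0.4, 0.3), (0.6, 0.5)]
        result = compare_gene_sets(pairs)
        assert result.mean_in_set == pytest.approx(0.4)
        assert result.mean_overall == pytest.approx(0.3)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            compare_gene_sets([(0.1, 0.1), (0.2, 0.2)])


class TestNullCalibration:
    def test_rank_sum_type_one_error(self):
        """Under the null the per-replicate rejection rate stays near alpha."""
        rng = np.random.default_rng(123)
        # background much larger than focal: keeps focal/sample overlap (and
        # the rank ties it induces) negligible, where the nominal size applies
        background = rng.lognormal(5.3, 0.6, size=2000)
        alpha = 0.05
        fractions = []
        for trial in range(200):
            focal = rng.choice(background, size=25, replace=False)
            result = compare_intron_lengths(
                focal, background, reps=10, seed=int(rng.integers(2**31))
            )
            fractions.append(np.mean(np.array(result.p_values) < alpha))
        mean_rej = float(np.mean(fractions))
        se = float(np.std(fractions) / np.sqrt(len(fractions)))
        assert abs(mean_rej - alpha) <= max(3 * se, 0.02)
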