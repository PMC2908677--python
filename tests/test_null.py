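import math

import numpy as np
import pytest

from puf3regulon.io import SpeciesDataset
from puf3regulon.motif import WindowCounts, compile_profile
from puf3regulon.null_model import (
    GCModel,
    estimate_gc,
    gc_vs_target_regression,
    generate_null,
    window_enrichment_test,
)

from conftest import random_sequences


def hypergeom_upper_tail(k, M, K, n):
    """Direct-summation oracle: P(X >= k) for X ~ Hypergeom(M, K, n)."""
    total = 0.0
    denom = math.comb(M, n)
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / denom
    return total


class TestEstimateGC:
    def _ds(self, seqs):
        return SpeciesDataset(species_id="s", downstream={f"g{i}": s for i, s in enumerate(seqs)})

    def test_balanced_sequences(self):
        assert estimate_gc(self._ds(["ACGT", "ACGT"])).gc == 0.5

    def test_at_only(self):
        assert estimate_gc(self._ds(["AAAA"])).gc == 0.0

    def test_n_excluded_from_both_sides(self):
        assert estimate_gc(self._ds(["ANGC"])).gc == pytest.approx(2 / 3)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError, match="zero countable"):
            estimate_gc(self._ds(["NNNN"]))

    def test_utr250_uses_only_first_250_bases(self):
        seq = "A" * 250 + "G" * 750
        assert estimate_gc(self._ds([seq]), mode="utr250").gc == 0.0
        assert estimate_gc(self._ds([seq]), mode="full_region").gc == 0.75

    def test_per_window_vector(self):
        seq = "A" * 50 + "G" * 50 + "AG" * 450
        model = estimate_gc(self._ds([seq]), mode="per_window")
        assert model.gc[0] == 0.0
        assert model.gc[1] == 1.0
        assert model.gc[2:] == pytest.approx(0.5)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            estimate_gc(self._ds(["ACGT"]), mode="bogus")


class TestGenerateNull:
    def test_same_seed_identical_counts(self, default_profile):
        model = GCModel("full_region", 0.4)
        a = generate_null(model, default_profile, n=200, seed=42)
        b = generate_null(model, default_profile, n=200, seed=42)
        assert np.array_equal(a.counts.counts, b.counts.counts)

    def test_gc_one_yields_no_matches(self, default_profile):
        null = generate_null(GCModel("full_region", 1.0), default_profile, n=100, seed=0)
        assert null.counts.counts.sum() == 0

    def test_match_frequency_agrees_with_closed_form(self, default_profile):
        # per-position match probability Pi_i P(allowed_i | gc) within 3 binomial sd
        gc, n = 0.2, 3000
        null = generate_null(GCModel("full_region", gc), default_profile, n=n, seed=5)
        p = default_profile.match_probability(gc)
        eligible = null.counts.eligible_positions.sum()
        expected = eligible * p
        sd = math.sqrt(eligible * p * (1 - p))
        assert abs(null.counts.counts.sum() - expected) <= 3 * sd

    def test_expected_counts_decrease_monotonically_in_gc(self, default_profile):
        probs = [default_profile.match_probability(gc) for gc in np.arange(0.2, 0.81, 0.1)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_per_window_mode_respects_window_composition(self, default_profile):
        # motif-friendly composition in window 0, pure GC elsewhere: matches
        # can only occur in window 0
        gc = np.array([0.3] + [1.0] * 19)
        null = generate_null(GCModel("per_window", gc), default_profile, n=2000, seed=9)
        assert null.counts.counts[0] > 0
        # window 1 onward cannot match; a match straddling the 50-bp boundary
        # would need A/T bases inside the GC-only block
        assert null.counts.counts[1:].sum() == 0

    def test_invalid_n(self, default_profile):
        with pytest.raises(ValueError):
            generate_null(GCModel("full_region", 0.5), default_profile, n=0)


class TestWindowEnrichmentTest:
    def _wc(self, counts, eligible, window=50, region=100):
        return WindowCounts(window_size=window, region_length=region,
                            counts=counts, eligible_positions=eligible, n_genes=1)

    def test_zero_observed_gives_p_one(self):
        obs = self._wc([0, 0], [1000, 1000])
        null = self._wc([0, 0], [10000, 10000])
        table = window_enrichment_test(obs, null)
        assert table["p_raw"].tolist() == [1.0, 1.0]

    def test_p_equals_hypergeometric_tail_by_direct_summation(self):
        obs = self._wc([10, 0], [1000, 1000])
        null = self._wc([10, 0], [10000, 10000])
        table = window_enrichment_test(obs, null)
        oracle = hypergeom_upper_tail(10, 11000, 20, 1000)
        assert table["p_raw"][0] == pytest.approx(oracle, rel=1e-10)

    def test_bonferroni_is_multiplication_capped_at_one(self):
        obs = self._wc([10, 10], [1000, 1000])
        null = self._wc([10, 10], [10000, 10000])
        table = window_enrichment_test(obs, null, bonferroni_n=20)
        assert table["p_bonferroni"][0] == pytest.approx(min(1.0, table["p_raw"][0] * 20))

    def test_significance_flag_matches_alpha(self):
        obs = self._wc([50, 0], [1000, 1000])
        null = self._wc([10, 0], [10000, 10000])
        table = window_enrichment_test(obs, null, alpha=0.01)
        assert bool(table["significant"][0]) == bool(table["p_bonferroni"][0] < 0.01)

    def test_geometry_mismatch_rejected(self):
        obs = self._wc([0], [100], window=100, region=100)
        null = self._wc([0, 0], [100, 100], window=50, region=100)
        with pytest.raises(ValueError, match="geometry"):
            window_enrichment_test(obs, null)


class TestGCRegression:
    def _species(self, gc, n, seed, species_id):
        seqs = random_sequences(gc, n, 1000, seed)
        return SpeciesDataset(
            species_id=species_id, downstream={f"g{i}": s for i, s in enumerate(seqs)}
        )

    def test_slope_negative_for_at_rich_profile(self, default_profile):
        datasets = [
            self._species(gc, 150, seed=i, species_id=f"s{i}")
            for i, gc in enumerate([0.25, 0.35, 0.45, 0.55])
        ]
        fit = gc_vs_target_regression(datasets, default_profile)
        assert fit.slope < 0
        assert 0 <= fit.r_squared <= 1

    def test_fewer_than_three_species_rejected(self, default_profile):
        datasets = [self._species(0.3, 10, seed=i, species_id=f"s{i}") for i in range(2)]
        with pytest.raises(ValueError, match="3 species"):
            gc_vs_target_regression(datasets, default_profile)

    def test_zero_gc_variance_rejected(self, default_profile):
        base = random_sequences(0.4, 10, 500, seed=1)
        datasets = [
            SpeciesDataset(species_id=f"s{i}", downstream={f"g{j}": s for j, s in enumerate(base)})
            for i in range(3)
        ]
        with pytest.raises(ValueError, match="zero variance"):
            gc_vs_target_regression(datasets, default_profile)


class TestTypeIErrorSmall:
    def test_null_observed_rarely_significant(self, default_profile):
        """Species drawn from the null GC model: Bonferroni hits stay rare."""
        gc = 0.38
        n_sig = total = 0
        for seed in range(20):
            obs_null = generate_null(GCModel("full_region", gc), default_profile,
                                     n=200, seed=1000 + seed)
            big_null = generate_null(GCModel("full_region", gc), default_profile,
                                     n=2000, seed=2000 + seed)
            table = window_enrichment_test(obs_null.counts, big_null, alpha=0.01)
            n_sig += int(table["significant"].sum())
            total += len(table)
        frac = n_sig / total
        assert frac <= 0.01 + 3 * math.sqrt(0.01 * 0.99 / total)
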