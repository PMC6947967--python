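"""GBS read simulation, genotype calling, correction and metrics."""
import numpy as np
import pytest

from gbsim import GenomeSpec
from gbsim.gbs import (DEFAULT_DISTANCE_FRACTIONS, MISSING, _het_call,
                       accuracy_summary, call_genotypes, correct_genotypes,
                       corrected_dosage_matrix, estimate_freq_from_gbs,
                       mask_low_reads, mean_gap_bp, round_dosages,
                       sample_gbs_positions, simulate_depths)


class TestPanelPlacement:
    def test_mean_gap_matches_weighted_table(self):
        assert mean_gap_bp() == pytest.approx(62015.0)

    def test_panel_size_near_genome_length_over_mean_gap(self, rng):
        spec = GenomeSpec()
        chrom, pos = sample_gbs_positions(spec, rng)
        expected = spec.genome_length_bp / mean_gap_bp()
        assert len(pos) == pytest.approx(expected, rel=0.05)
        # positions strictly increasing within chromosome, on the grid
        for c in range(spec.n_chromosomes):
            p = pos[chrom == c]
            assert np.all(np.diff(p) > 0)
            assert np.all(p % spec.grid_spacing_bp == 0)
            assert p.max() <= spec.chrom_length_bp

    def test_single_small_gap_bin_gives_constant_spacing(self, rng):
        spec = GenomeSpec(n_chromosomes=1, chrom_length_cm=1.0)
        chrom, pos = sample_gbs_positions(spec, rng, fractions=((500, 1.0),))
        assert np.all(np.diff(pos) == 500)

    def test_invalid_fractions_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_gbs_positions(GenomeSpec(), rng, fractions=((500, 0.5), (2500, 0.4)))


class TestDepthsAndCalling:
    def test_zero_read_fraction_matches_poisson_zero_class(self, rng):
        for x, expected in [(2, np.exp(-2)), (5, np.exp(-5))]:
            d = simulate_depths(1000, 1000, x, rng)
            assert (d == 0).mean() == pytest.approx(expected, abs=3e-3)
            assert d.mean() == pytest.approx(x, rel=0.01)

    def test_huge_depth_never_zero(self, rng):
        assert (simulate_depths(100, 100, 1e6, rng) == 0).sum() == 0

    @pytest.mark.parametrize("u,n,expected", [
        (0.20, 2, 0),   # u <= (1/2)^n -> aa
        (0.25, 2, 0),   # boundary included
        (0.30, 2, 2),   # (1/2)^n < u < 2(1/2)^n -> AA
        (0.60, 2, 1),   # otherwise heterozygote kept
        (0.49, 1, 0), (0.51, 1, 2), (0.99, 1, 2),  # n=1: never called Aa
    ])
    def test_het_calling_rule(self, u, n, expected):
        assert _het_call(np.array([u]), np.array([n]))[0] == expected

    def test_homozygotes_and_missing(self, rng):
        truth = rng.integers(0, 3, size=(300, 50)).astype(np.int8)
        depths = simulate_depths(300, 50, 2, rng)
        calls = call_genotypes(truth, depths, rng)
        assert np.all(calls[depths == 0] == MISSING)
        hom = (truth != 1) & (depths > 0)
        assert np.array_equal(calls[hom], truth[hom])
        assert set(np.unique(calls)) <= {-1, 0, 1, 2}

    def test_het_miscall_rate_matches_poisson_mixture(self, rng):
        """Fraction of covered true hets miscalled ~ 2(e^{-x/2}-e^{-x})/(1-e^{-x})."""
        x = 2.0
        truth = np.ones((2000, 500), dtype=np.int8)
        depths = simulate_depths(2000, 500, x, rng)
        calls = call_genotypes(truth, depths, rng)
        covered = depths > 0
        rate = (calls[covered] != 1).mean()
        expected = 2 * (np.exp(-x / 2) - np.exp(-x)) / (1 - np.exp(-x))
        assert rate == pytest.approx(expected, abs=0.003)

    def test_negative_reads_rejected(self, rng):
        with pytest.raises(ValueError):
            call_genotypes(np.zeros((2, 2), np.int8), np.full((2, 2), -1), rng)


class TestMaskLowReads:
    def test_zero_threshold_is_identity(self, rng):
        truth = rng.integers(0, 3, (50, 20)).astype(np.int8)
        depths = simulate_depths(50, 20, 4, rng)
        calls = call_genotypes(truth, depths, rng)
        assert np.array_equal(mask_low_reads(calls, depths, 0), calls)

    def test_masked_fraction_matches_poisson_mass(self, rng):
        depths = simulate_depths(1000, 1000, 4, rng)
        calls = np.zeros_like(depths, dtype=np.int8)
        calls[depths == 0] = MISSING
        masked = mask_low_reads(calls, depths, 2)
        extra = (masked == MISSING).mean() - (calls == MISSING).mean()
        expected = 4 * np.exp(-4) + 8 * np.exp(-4)  # P(n=1) + P(n=2)
        assert extra == pytest.approx(expected, abs=2e-3)

    def test_all_depth_one_fully_masked(self):
        calls = np.ones((3, 3), dtype=np.int8)
        assert np.all(mask_low_reads(calls, np.ones((3, 3), int), 1) == MISSING)


class TestGenotypeCorrection:
    def test_printed_formula_spot_values(self):
        calls = np.array([[0, 2, 1]], dtype=np.int8)
        depths = np.array([[1, 1, 1]])
        p = np.full(3, 0.5)
        gc = correct_genotypes(calls, depths, p)
        assert gc[0, 0] == pytest.approx(0.5)
        assert gc[0, 1] == pytest.approx(1.5)
        assert gc[0, 2] == 1.0

    def test_heterozygote_calls_stay_exactly_one(self, rng):
        calls = np.ones((20, 10), dtype=np.int8)
        depths = rng.integers(1, 10, (20, 10))
        gc = correct_genotypes(calls, depths, rng.random(10))
        assert np.all(gc == 1.0)

    def test_dosage_bounds_and_monotonicity_in_depth(self):
        p = np.array([0.3])
        n = np.arange(1, 30)[:, None]
        gc_aa = correct_genotypes(np.zeros((29, 1), np.int8), n, p)[:, 0]
        gc_AA = correct_genotypes(np.full((29, 1), 2, np.int8), n, p)[:, 0]
        assert np.all((gc_aa >= 0) & (gc_AA <= 2))
        assert np.all(np.diff(gc_aa) < 0) and np.all(np.diff(gc_AA) > 0)
        assert gc_aa[-1] == pytest.approx(0.0, abs=1e-6)
        assert gc_AA[-1] == pytest.approx(2.0, abs=1e-6)

    def test_degenerate_frequencies_collapse(self):
        calls = np.array([[0, 2]], dtype=np.int8)
        depths = np.array([[3, 3]])
        assert np.allclose(correct_genotypes(calls, depths, np.array([0.0, 0.0])), 0.0)
        assert np.allclose(correct_genotypes(calls, depths, np.array([1.0, 1.0])), 2.0)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            correct_genotypes(np.zeros((1, 1), np.int8), np.ones((1, 1)), np.array([1.5]))

    def test_missing_preserved_and_chunked_matches_direct(self, rng):
        truth = rng.integers(0, 3, (40, 300)).astype(np.int8)
        depths = simulate_depths(40, 300, 2, rng)
        calls = call_genotypes(truth, depths, rng)
        p = np.clip(truth.mean(axis=0) / 2, 0.01, 0.99)
        direct = correct_genotypes(calls, depths, p)
        chunked = corrected_dosage_matrix(calls, depths, p, chunk_loci=7)
        assert np.isnan(direct[calls == MISSING]).all()
        np.testing.assert_allclose(chunked, direct.astype(np.float32),
                                   rtol=1e-6, equal_nan=True)

    def test_posterior_mean_beats_raw_calls_in_mse(self, rng):
        """Conditional expectation minimizes MSE at every mean depth."""
        p_true = 0.3
        n_ind, n_loc = 4000, 50
        haps = (rng.random((n_ind, 2, n_loc)) < p_true).astype(np.int8)
        truth = haps.sum(axis=1)
        for x in (2, 4, 5, 10):
            depths = simulate_depths(n_ind, n_loc, x, rng)
            calls = call_genotypes(truth, depths, rng)
            gc = correct_genotypes(calls, depths, np.full(n_loc, p_true))
            obs = calls != MISSING
            mse_gc = np.mean((gc[obs] - truth[obs]) ** 2)
            mse_raw = np.mean((calls[obs] - truth[obs]) ** 2.0)
            assert mse_gc <= mse_raw + 1e-12


class TestRounding:
    def test_rounding_rules(self):
        d = np.array([[0.49, 0.5, 1.0, 1.5, 1.51, np.nan]])
        assert np.array_equal(round_dosages(d)[0], [0, 0, 1, 2, 2, MISSING])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            round_dosages(np.array([2.5]))

    def test_tie_resolves_toward_called_homozygote(self):
        # Gc_aa = 0.5 at p = 0.5, n = 1 rounds to the aa call
        gc = correct_genotypes(np.array([[0]], np.int8), np.array([[1]]), np.array([0.5]))
        assert round_dosages(gc)[0, 0] == 0


class TestAlleleFrequency:
    def test_symmetric_calls_give_half(self):
        calls = np.array([[2, 0, 1, 1]], dtype=np.int8).T
        assert estimate_freq_from_gbs(calls)[0] == pytest.approx(0.5)

    def test_all_AA_gives_one(self):
        assert estimate_freq_from_gbs(np.full((5, 1), 2, np.int8))[0] == 1.0

    def test_all_missing_policy(self):
        calls = np.full((4, 1), MISSING, dtype=np.int8)
        with pytest.raises(ValueError):
            estimate_freq_from_gbs(calls)
        assert np.isnan(estimate_freq_from_gbs(calls, on_all_missing="nan")[0])

    @pytest.mark.parametrize("p_true", [0.1, 0.3, 0.5])
    def test_estimator_unbiased_under_miscalling(self, rng, p_true):
        """Het-miscall inflation cancels in P(AA) - P(aa): |bias| < 0.005."""
        n_ind, n_loc = 100_000, 8
        haps = (rng.random((n_ind, 2, n_loc)) < p_true).astype(np.int8)
        truth = haps.sum(axis=1)
        depths = simulate_depths(n_ind, n_loc, 2, rng)
        calls = call_genotypes(truth, depths, rng)
        p_hat = estimate_freq_from_gbs(calls)
        assert abs(p_hat.mean() - p_true) < 0.005


class TestAccuracySummary:
    def test_perfect_data(self, rng):
        truth = rng.integers(0, 3, (30, 20)).astype(np.int8)
        acc = accuracy_summary(truth.copy(), truth)
        assert acc.correct_rate == 1.0 and acc.missing_rate == 0.0
        assert acc.correlation == pytest.approx(1.0)

    def test_rates_partition_all_entries(self, rng):
        truth = rng.integers(0, 3, (200, 100)).astype(np.int8)
        depths = simulate_depths(200, 100, 2, rng)
        calls = call_genotypes(truth, depths, rng)
        acc = accuracy_summary(calls, truth)
        assert acc.missing_rate + acc.incorrect_rate + acc.correct_rate \
            == pytest.approx(1.0, abs=1e-12)

    def test_chunking_invariance(self, rng):
        truth = rng.integers(0, 3, (50, 130)).astype(np.int8)
        depths = simulate_depths(50, 130, 2, rng)
        calls = call_genotypes(truth, depths, rng)
        a = accuracy_summary(calls, truth, chunk_loci=7)
        b = accuracy_summary(calls, truth, chunk_loci=10_000)
        assert (a.missing_rate, a.incorrect_rate, a.correct_rate) \
            == (b.missing_rate, b.incorrect_rate, b.correct_rate)
        assert a.correlation == pytest.approx(b.correlation, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            accuracy_summary(np.ones((5, 5), np.int8), np.ones((5, 5), np.int8))
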