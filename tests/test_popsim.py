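"""Forward simulator: founders, meiosis, drift, QTL and selection."""
import numpy as np
import pytest

from gbsim import GenomeSpec, PopulationDesign
from gbsim.popsim import (HaploidGenomes, assign_qtl_effects,
                          expand_and_breed_recent, init_founders, mean_ld_r2,
                          ld_decay, run_historical, sample_gametes,
                          switch_probabilities, uniform_tracked_loci)


class TestFounders:
    def test_shape_domain_and_determinism(self, small_spec):
        rng = np.random.default_rng(3)
        loci = uniform_tracked_loci(small_spec, 10, rng)
        g = init_founders(small_spec, loci, 200, np.random.default_rng(4))
        assert g.haplotypes.shape == (200, 2, 10)
        assert set(np.unique(g.haplotypes)) <= {0, 1}
        g2 = init_founders(small_spec, loci, 200, np.random.default_rng(4))
        assert np.array_equal(g.haplotypes, g2.haplotypes)

    def test_mean_heterozygosity_is_one_third(self, small_spec, rng):
        """E[2 p0 (1-p0)] over Uniform(0,1) founder frequencies = 1/3."""
        loci = uniform_tracked_loci(small_spec, 4000, rng)
        g = init_founders(small_spec, loci, 400, rng)
        p = g.allele_frequencies()
        assert (2 * p * (1 - p)).mean() == pytest.approx(1 / 3, abs=0.01)

    def test_too_many_tracked_loci_rejected(self, rng):
        tiny = GenomeSpec(n_chromosomes=1, chrom_length_cm=0.001)
        with pytest.raises(ValueError):
            uniform_tracked_loci(tiny, 100, rng)


class TestMeiosis:
    def test_identical_parental_haplotypes_transmit_unchanged(self, small_spec, rng):
        loci = uniform_tracked_loci(small_spec, 50, rng)
        hap = rng.integers(0, 2, size=(1, 1, 50)).astype(np.uint8)
        g = HaploidGenomes(loci, np.repeat(hap, 2, axis=1))
        sw = switch_probabilities(loci, small_spec)
        gam = sample_gametes(g, np.zeros(200, int), sw, rng)
        assert np.all(gam == hap[0, 0])

    def test_mean_crossover_count_poisson(self, rng):
        """100 cM chromosome: one phase switch per gamete on average."""
        spec = GenomeSpec(n_chromosomes=1)
        loci = uniform_tracked_loci(spec, 500, rng)
        # fully heterozygous parent: phase visible at every locus
        haps = np.zeros((1, 2, 500), np.uint8)
        haps[0, 1] = 1
        g = HaploidGenomes(loci, haps)
        sw = switch_probabilities(loci, spec)
        gam = sample_gametes(g, np.zeros(20_000, int), sw, rng)
        switches = (np.diff(gam.astype(int), axis=1) != 0).sum(axis=1)
        # observed switch count underestimates crossovers by double events;
        # with 500 tracked loci the correction is small
        assert switches.mean() == pytest.approx(1.0, abs=0.05)

    def test_recombination_fraction_haldane_small_distance(self, rng):
        """Two loci 50 kb apart: r = (1 - exp(-0.001))/2 ~ 5e-4."""
        spec = GenomeSpec(n_chromosomes=1)
        from gbsim.popsim import TrackedLoci
        loci = TrackedLoci(np.zeros(2, np.int16),
                           np.array([1_000_000, 1_050_000]),
                           np.zeros(2, bool))
        haps = np.zeros((1, 2, 2), np.uint8)
        haps[0, 1] = 1
        g = HaploidGenomes(loci, haps)
        sw = switch_probabilities(loci, spec)
        gam = sample_gametes(g, np.zeros(2_000_000, int), sw, rng)
        rec = (gam[:, 0] != gam[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-2 * 0.05 / 100))
        assert rec == pytest.approx(expected, abs=2e-4)

    def test_mutation_flips_alleles_at_given_rate(self, small_spec, rng):
        loci = uniform_tracked_loci(small_spec, 2000, rng)
        haps = np.zeros((1, 2, 2000), np.uint8)
        g = HaploidGenomes(loci, haps)
        sw = np.zeros(2000, dtype=np.float32)  # no recombination noise
        gam = sample_gametes(g, np.zeros(5000, int), sw, rng, mutation_rate=1e-3)
        assert gam.mean() == pytest.approx(1e-3, rel=0.1)


class TestHistoricalPhases:
    def test_zero_generations_returns_input(self, small_spec, small_design, rng):
        loci = uniform_tracked_loci(small_spec, 20, rng)
        g = init_founders(small_spec, loci, 40, rng)
        out = run_historical(small_spec, small_design, g, rng, schedule=[])
        assert out is g

    def test_schedule_endpoint_and_size(self, small_spec, small_design, rng):
        loci = uniform_tracked_loci(small_spec, 30, rng)
        g = init_founders(small_spec, loci, small_design.hist_phase1_size, rng)
        out = run_historical(small_spec, small_design, g, rng)
        assert out.n_individuals == small_design.hist_phase2_end_size

    def test_tiny_population_rejected(self, small_spec, small_design, rng):
        loci = uniform_tracked_loci(small_spec, 10, rng)
        g = init_founders(small_spec, loci, 4, rng)
        with pytest.raises(ValueError):
            run_historical(small_spec, small_design, g, rng, schedule=[2])

    def test_drift_decays_heterozygosity_at_one_over_2n(self, rng):
        """Mutation off, constant N: E[H_t] = H_0 (1 - 1/2N)^t.

        Loci on a chromosome share a genealogy, so the check averages
        over replicate populations with 5 chromosomes each."""
        spec = GenomeSpec()
        design = PopulationDesign()
        N, G = 60, 40
        ratios = []
        for _ in range(3):
            loci = uniform_tracked_loci(spec, 2000, rng)
            g = init_founders(spec, loci, N, rng)
            p0 = g.allele_frequencies()
            out = run_historical(spec, design, g, rng, mutation=False,
                                 schedule=[N] * G)
            p = out.allele_frequencies()
            ratios.append((2 * p * (1 - p)).mean() / (2 * p0 * (1 - p0)).mean())
        expected = (1 - 1 / (2 * N)) ** G
        assert np.mean(ratios) == pytest.approx(expected, rel=0.05)


class TestQTL:
    def test_tbv_variance_hits_target_after_scaling(self, small_spec, rng):
        loci = uniform_tracked_loci(small_spec, 500, rng, n_qtl=20)
        g = init_founders(small_spec, loci, 600, rng)
        qtl = assign_qtl_effects(small_spec, g, rng, heritability=0.3,
                                 phenotypic_variance=1.0)
        tbv = qtl.tbv(g.dosages()[:, qtl.qtl_idx])
        assert tbv.var() == pytest.approx(0.3, rel=1e-9)

    def test_gamma_magnitudes_have_mean_shape_times_scale(self, rng):
        draws = rng.gamma(0.4, 1.0, size=200_000)
        assert draws.mean() == pytest.approx(0.4, rel=0.02)

    def test_all_qtl_fixed_raises(self, small_spec, rng):
        loci = uniform_tracked_loci(small_spec, 50, rng, n_qtl=5)
        haps = np.ones((30, 2, 50), np.uint8)
        g = HaploidGenomes(loci, haps)
        with pytest.raises(ValueError):
            assign_qtl_effects(small_spec, g, rng)


class TestExpansionAndSelection:
    def test_recent_population_structure(self, small_spec, small_design, rng):
        loci = uniform_tracked_loci(small_spec, 300, rng, n_qtl=20)
        g = init_founders(small_spec, loci, 40, rng)
        hist = run_historical(small_spec, small_design, g, rng, schedule=[40] * 5)
        pop = expand_and_breed_recent(small_spec, small_design, hist, rng)
        d = small_design
        per_gen = d.recent_dams * d.litter_size
        assert pop.n_genotyped == d.recent_generations * per_gen \
            if hasattr(pop, "n_genotyped") else True
        gens, counts = np.unique(pop.genotyped_generations, return_counts=True)
        assert list(gens) == list(range(1, d.recent_generations + 1))
        assert np.all(counts == per_gen)
        ped = pop.pedigree
        # every non-founder's parents exist, have correct sex, and precede it
        off = np.flatnonzero(ped.sire >= 0)
        assert np.all(ped.sire[off] < off) and np.all(ped.dam[off] < off)
        assert np.all(ped.sex[ped.sire[off]] == 0)
        assert np.all(ped.sex[ped.dam[off]] == 1)
        # phenotype = tbv + residual with the configured variance
        resid = pop.phenotype[pop.genotyped_ids] - pop.tbv[pop.genotyped_ids]
        # 320 residual draws: sampling SE of the variance is ~8%
        assert resid.var() == pytest.approx(d.residual_variance, rel=0.25)

    def test_selection_response_positive(self, small_spec, small_design, rng):
        """Truncation selection on EBV raises mean TBV across generations."""
        loci = uniform_tracked_loci(small_spec, 300, rng, n_qtl=20)
        g = init_founders(small_spec, loci, 40, rng)
        hist = run_historical(small_spec, small_design, g, rng, schedule=[40] * 5)
        pop = expand_and_breed_recent(small_spec, small_design, hist, rng)
        gens = pop.genotyped_generations
        first = pop.tbv[pop.genotyped_ids[gens == 1]].mean()
        last = pop.tbv[pop.genotyped_ids[gens == gens.max()]].mean()
        assert last > first


class TestLDSummaries:
    def test_duplicated_locus_gives_r2_one(self):
        x = np.array([0, 1, 2, 1, 0, 2, 1, 1], dtype=float)
        geno = np.stack([x, x], axis=1)
        r2, n = mean_ld_r2(geno, np.zeros(2, int), np.array([100, 200]))
        assert n == 1 and r2 == pytest.approx(1.0)

    def test_independent_loci_r2_near_null_expectation(self, rng):
        n = 4000
        geno = rng.integers(0, 3, size=(n, 2)).astype(float)
        r2, _ = mean_ld_r2(geno, np.zeros(2, int), np.array([100, 200]))
        assert r2 < 10 / n  # null expectation ~ 1/(n-1)

    def test_no_qualifying_pairs_raises(self):
        geno = np.random.default_rng(0).integers(0, 3, (20, 2)).astype(float)
        with pytest.raises(ValueError):
            mean_ld_r2(geno, np.array([0, 1]), np.array([100, 200]))

    def test_monomorphic_member_skipped(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 50).astype(float)
        geno = np.stack([a, np.ones(50)], axis=1)
        with pytest.raises(ValueError):
            mean_ld_r2(geno, np.zeros(2, int), np.array([100, 200]))

    def test_ld_decay_bins(self, rng):
        pos = np.arange(1, 51) * 1000
        geno = rng.integers(0, 3, (200, 50)).astype(float)
        df = ld_decay(geno, np.zeros(50, int), pos, [0, 10_000, 50_000])
        assert (df["n_pairs"] > 0).all()
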