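"""Simulator checks: Mendelian selfing ratios, Haldane recombination
fractions, drift unbiasedness, Wright-Fisher heterozygosity decay, and the
equivalence of the fast count-based engine with the individual-based one."""
import numpy as np
import pytest

import wqscan as w
from wqscan.sim import hwe_population


def _protocol(n_s0=2000, n_sel=20, selfing=0, n_next=2000, ncyc=1):
    spec = w.CycleSpec(n_s0_plants=n_s0, n_selected=n_sel,
                       selfing_generations=selfing)
    return w.BreedingProtocol([spec] * ncyc, next_cycle_pop_size=n_next)


class TestMeiosis:
    def test_zero_distance_never_recombines(self, rng):
        gmap = w.GeneticMap(["c1", "c1"], [10.0, 10.0], [1, 2])
        parent = np.array([[0, 0], [1, 1]], dtype=np.int8)
        gams = np.array([w.meiosis_gamete(parent, gmap, rng) for _ in range(500)])
        assert (gams[:, 0] == gams[:, 1]).all()

    @pytest.mark.parametrize("gmap,expected", [
        (w.GeneticMap(["c1", "c2"], [0.0, 0.0], [1, 1]), 0.5),
        (w.GeneticMap(["c1", "c1"], [0.0, 50.0], [1, 2]), 0.5 * (1 - np.exp(-1.0))),
    ])
    def test_recombinant_fraction(self, gmap, expected, rng):
        parent = np.tile(np.array([[0], [1]], dtype=np.int8), (1, 2))
        from wqscan.sim import _meiose_batch
        gams = _meiose_batch(np.tile(parent, (10000, 1, 1)), gmap, rng)
        frac = (gams[:, 0] != gams[:, 1]).mean()
        assert frac == pytest.approx(expected, abs=0.02)

    def test_length_mismatch_rejected(self, rng):
        gmap = w.GeneticMap(["c1"], [0.0], [1])
        with pytest.raises(ValueError):
            w.meiosis_gamete(np.zeros((2, 3), dtype=np.int8), gmap, rng)


class TestSelfing:
    def test_homozygote_unchanged(self, rng):
        g = np.array([0, 2, 2, 0])
        assert np.array_equal(w.self_single_seed_descent(g, 5, rng), g)

    @pytest.mark.parametrize("generations,expected", [(1, 0.5), (2, 0.25)])
    def test_heterozygosity_halves_each_generation(self, generations, expected, rng):
        g = np.ones(10000, dtype=int)
        out = w.self_single_seed_descent(g, generations, rng)
        assert (out == 1).mean() == pytest.approx(expected, abs=0.015)
        # allele frequency is preserved in expectation
        assert out.mean() / 2 == pytest.approx(0.5, abs=0.02)


class TestAdvanceCycle:
    def test_monomorphic_stays_monomorphic(self, rng):
        pop = w.PopulationState(np.full((50, 3), 2, dtype=np.int8))
        spec = w.CycleSpec(n_s0_plants=30, n_selected=5)
        nxt = w.advance_cycle(pop, spec, w.BreedingProtocol([spec], 40), rng)
        assert (nxt.dosages == 2).all()
        assert nxt.n_individuals == 40

    def test_drift_is_unbiased(self, rng):
        # mean next-cycle frequency over replicates stays at p0 = 0.5
        spec = w.CycleSpec(n_s0_plants=50, n_selected=10, selfing_generations=1)
        proto = w.BreedingProtocol([spec], next_cycle_pop_size=50)
        means = []
        for _ in range(2000):
            pop = hwe_population([0.5], 50, rng)
            nxt = w.advance_cycle(pop, spec, proto, rng)
            means.append(nxt.allele_frequencies()[0])
        assert np.mean(means) == pytest.approx(0.5, abs=0.01)

    def test_truncation_selection_raises_frequency(self, rng):
        arch = w.TraitArchitecture(qtl_loci=(0,), qtl_effects=(1.0,), h2_target=1.0)
        fn = w.make_truncation_fn(arch)
        spec = w.CycleSpec(n_s0_plants=100, n_selected=10, selfing_generations=1)
        proto = w.BreedingProtocol([spec], next_cycle_pop_size=100)
        freqs = []
        for _ in range(300):
            pop = hwe_population([0.5], 100, rng)
            nxt = w.advance_cycle(pop, spec, proto, rng, selection_fn=fn)
            freqs.append(nxt.allele_frequencies()[0])
        assert np.mean(freqs) > 0.55

    def test_selected_families_returned(self, rng):
        pop = hwe_population([0.5] * 4, 60, rng)
        spec = w.CycleSpec(n_s0_plants=40, n_selected=6)
        nxt, fams = w.advance_cycle(pop, spec, w.BreedingProtocol([spec], 60),
                                    rng, return_selected=True)
        assert fams.shape == (6, 4)
        assert np.isin(fams, (0, 1, 2)).all()


class TestDriftTrajectories:
    def test_absorbing_states(self, rng, wqs_protocol):
        out = w.simulate_drift_trajectories([0.0, 1.0], wqs_protocol, 300, rng)
        assert (out[0] == 0).all() and (out[1] == 1).all()

    def test_invalid_frequency_rejected(self, rng, wqs_protocol):
        with pytest.raises(ValueError):
            w.simulate_drift_trajectories([1.2], wqs_protocol, 10, rng)

    def test_martingale(self, rng, wqs_protocol):
        # replicate-mean final frequency within 3 MC standard errors of p0
        for p0 in (0.2, 0.5, 0.8):
            out = w.simulate_drift_trajectories([p0], wqs_protocol, 8000, rng).ravel()
            se = out.std() / np.sqrt(out.size)
            assert abs(out.mean() - p0) < 3 * se

    def test_wright_fisher_heterozygosity_decay(self, rng):
        # bottleneck of N=20 random maters per cycle, large pools elsewhere:
        # E[D_t] = D0 (1 - 1/(2N))^t
        proto = _protocol(n_s0=20000, n_sel=20, selfing=0, n_next=20000, ncyc=2)
        pf = w.simulate_drift_trajectories(np.full(1, 0.5), proto, 20000, rng)
        d = 2 * pf * (1 - pf)
        expected = 0.5 * (1 - 1 / 40) ** 2
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean() - expected) < 3 * se

    def test_selfing_inflates_drift(self, rng):
        # selfed family representatives carry extra homozygosity, so drift
        # variance per cycle exceeds the no-selfing case
        base = _protocol(n_s0=20000, n_sel=20, selfing=0, n_next=20000)
        selfed = _protocol(n_s0=20000, n_sel=20, selfing=2, n_next=20000)
        v0 = w.simulate_drift_trajectories(np.full(1, 0.5), base, 8000, rng).var()
        v2 = w.simulate_drift_trajectories(np.full(1, 0.5), selfed, 8000, rng).var()
        assert v2 > v0 * 1.3

    def test_wqs_bottleneck_dominates_founder_count(self, rng, wqs_protocol):
        # one-cycle diversity loss far exceeds an idealized population of
        # size n_s0_plants = 450
        proto = w.BreedingProtocol([wqs_protocol.cycles[0]],
                                   next_cycle_pop_size=450)
        pf = w.simulate_drift_trajectories(np.full(1, 0.5), proto, 20000, rng)
        d = 2 * pf * (1 - pf)
        loss = 1 - d.mean() / 0.5
        assert loss > 1 / (2 * 450)

    def test_fast_engine_matches_individual_engine(self, rng):
        # the count-based engine is distributionally equivalent to running
        # advance_cycle: compare mean and variance of final frequencies
        spec = w.CycleSpec(n_s0_plants=60, n_selected=8, selfing_generations=2)
        proto = w.BreedingProtocol([spec], next_cycle_pop_size=60)
        fast = w.simulate_drift_trajectories([0.3], proto, 6000, rng).ravel()
        slow = []
        pop0 = None
        for _ in range(3000):
            pop = hwe_population([0.3], 60, rng)
            slow.append(w.advance_cycle(pop, spec, proto, rng).allele_frequencies()[0])
        slow = np.asarray(slow)
        assert fast.mean() == pytest.approx(slow.mean(), abs=0.01)
        assert fast.var() == pytest.approx(slow.var(), rel=0.15)

    def test_deterministic_given_seed(self, wqs_protocol):
        a = w.simulate_drift_trajectories([0.4, 0.6], wqs_protocol, 50,
                                          np.random.default_rng(99))
        b = w.simulate_drift_trajectories([0.4, 0.6], wqs_protocol, 50,
                                          np.random.default_rng(99))
        assert np.array_equal(a, b)


class TestWqsGenomes:
    def test_row_counts_and_labels(self, small_wqs_geno):
        # 20 families recorded per cycle for 3 transitions + the final cycle
        assert small_wqs_geno.n_samples == 80
        assert small_wqs_geno.cycle_order == ["C2", "C3", "C4", "C5"]
        counts = small_wqs_geno.samples["cycle"].value_counts()
        assert (counts == 20).all()

    def test_first_cycle_frequencies_match_spectrum_mean(self, wqs_protocol):
        rng = np.random.default_rng(21)
        gmap = w.GeneticMap.uniform(5000)
        geno = w.simulate_wqs_genomes(wqs_protocol, gmap, rng,
                                      founder_spectrum=lambda n, r: r.uniform(0.1, 0.9, n))
        freqs = w.estimate_allele_frequencies(geno, by_cycle=True)
        assert freqs.p["C2"].mean() == pytest.approx(0.5, abs=0.02)

    def test_mean_diversity_non_increasing_across_cycles(self, wqs_protocol):
        rng = np.random.default_rng(3)
        gmap = w.GeneticMap.uniform(400)
        first, last = [], []
        for _ in range(20):
            geno = w.simulate_wqs_genomes(wqs_protocol, gmap, rng)
            freqs = w.estimate_allele_frequencies(geno, by_cycle=True)
            d = w.diversity_scan(freqs, geno.cycle_order)
            first.append(d.summary.loc["C2", "mean_d"])
            last.append(d.summary.loc["C5", "mean_d"])
        assert np.mean(first) > np.mean(last)

    def test_deterministic_given_seed(self, wqs_protocol):
        gmap = w.GeneticMap.uniform(100)
        a = w.simulate_wqs_genomes(wqs_protocol, gmap, np.random.default_rng(5))
        b = w.simulate_wqs_genomes(wqs_protocol, gmap, np.random.default_rng(5))
        assert a.equals(b)


class TestPhenotypes:
    def test_zero_noise_gives_identical_plots_within_cell(self, small_wqs_geno, rng):
        pheno = w.simulate_phenotypes(small_wqs_geno, None, 2, 3, (4.0, 0.0, 0.0),
                                      rng, rep_effect_scale=0.0)
        spread = pheno.groupby(["family", "environment"])["trait"].std()
        assert (spread.fillna(0) < 1e-12).all()

    def test_zero_genetic_variance_recovers_null_H(self):
        # with components truncated at zero the null H carries a small
        # positive bias (~0.4*sqrt(2(1+1/(e-1))/(F-1)) at F families), so
        # "recovered as ~0" means: mean well below any real heritability and
        # a large share of datasets estimating exactly 0
        rng = np.random.default_rng(11)
        ids = [f"F{i}" for i in range(150)]
        geno = w.GenotypeMatrix(np.ones((150, 2)), ["a", "b"], ids, ["C2"] * 150)
        hs = []
        for _ in range(50):
            pheno = w.simulate_phenotypes(geno, None, 2, 3, (0.0, 1.0, 2.0), rng)
            hs.append(w.fit_family_varcomps(pheno, "trait").H)
        assert np.mean(hs) < 0.1
        assert np.mean(np.asarray(hs) == 0.0) > 0.3

    def test_qtl_architecture_sets_family_variance(self, small_wqs_geno, rng):
        arch = w.TraitArchitecture(qtl_loci=(1, 5, 9), qtl_effects=(1.0, -0.5, 2.0))
        pheno = w.simulate_phenotypes(small_wqs_geno, arch, 2, 2, (4.0, 0.0, 0.0), rng)
        fam_means = pheno.groupby("family")["trait"].mean()
        assert fam_means.var() == pytest.approx(4.0, rel=0.2)

    def test_negative_varcomp_rejected(self, small_wqs_geno, rng):
        with pytest.raises(ValueError):
            w.simulate_phenotypes(small_wqs_geno, None, 2, 3, (-1.0, 0.0, 1.0), rng)
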