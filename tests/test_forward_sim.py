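import numpy as np
import pytest
from scipy import stats

import adaptarch as aa
from adaptarch._recomb import meiosis
from adaptarch.forward_sim import (
    FitnessRegime,
    Population,
    evolve,
    evolve_module,
    gaussian_fitness,
    genotypic_value,
    module_fitness,
    next_generation,
    phenotype,
)
from adaptarch.trait_architecture import TraitArchitecture, build_module_architecture


def _regime(a=1.0, b=3.6, mean=0.0, var=1.0):
    return FitnessRegime.single_trait(a=a, b=b).anchor(mean, var)


class TestGenotypicValue:
    def test_reference_population_scores_zero(self):
        pop = Population(np.zeros((2, 10, 3), dtype=np.uint8))
        arch = TraitArchitecture(loci=[0, 1, 2], effect=[0.1, 0.2, 0.3], h2=0.5)
        assert np.all(genotypic_value(pop, arch) == 0)

    @pytest.mark.parametrize("d,expected", [(0.5, 1.0), (0.0, 0.0), (1.0, 2.0)])
    def test_heterozygote_dominance_scaling(self, d, expected):
        haps = np.zeros((2, 1, 1), dtype=np.uint8)
        haps[0, 0, 0] = 1  # one heterozygote
        arch = TraitArchitecture(loci=[0], effect=[1.0], h2=0.5, dominance=d)
        assert genotypic_value(Population(haps), arch)[0] == pytest.approx(expected)

    def test_homozygote_scores_two_alpha(self):
        haps = np.ones((2, 1, 1), dtype=np.uint8)
        arch = TraitArchitecture(loci=[0], effect=[0.7], h2=0.5, dominance=0.2)
        assert genotypic_value(Population(haps), arch)[0] == pytest.approx(1.4)

    def test_locus_mismatch_raises(self):
        pop = Population(np.zeros((2, 5, 2), dtype=np.uint8))
        arch = TraitArchitecture(loci=[0, 1, 2], effect=[1, 1, 1], h2=0.5)
        with pytest.raises(IndexError):
            genotypic_value(pop, arch)


class TestPhenotype:
    def test_zero_noise_is_identity(self):
        v = np.arange(5.0)
        assert np.array_equal(phenotype(v, 0.0, seed=1), v)

    def test_noise_variance(self):
        v = np.zeros(100_000)
        z = phenotype(v, 4.0, seed=2)
        assert np.var(z - v) == pytest.approx(4.0, abs=0.1)

    def test_offspring_midparent_regression_equals_h2(self, big_panel):
        # breeder's-equation oracle: slope of offspring on midparent = h2
        # (additive trait, random mating, no selection)
        from adaptarch.trait_architecture import (
            assign_environmental_variance,
            build_trait_architecture,
        )

        h2 = 0.65
        arch = build_trait_architecture(big_panel, M=60, shape=2.5, h2=h2, seed=3)
        rng = np.random.default_rng(4)
        n = 40_000
        sub = big_panel.alleles[:, arch.loci]
        parents = Population(sub[rng.integers(0, big_panel.n_haplotypes, size=(2, n))])
        vg = np.var(genotypic_value(parents, arch), ddof=1)
        sE2 = assign_environmental_variance(vg, h2)
        zp = phenotype(genotypic_value(parents, arch), sE2, rng)
        rfrac = big_panel.gmap.subset(arch.loci).recombination_fractions()
        mothers = rng.permutation(n)
        fathers = rng.permutation(n)
        child = np.stack(
            [
                meiosis(parents.haplotypes, mothers, rfrac, rng),
                meiosis(parents.haplotypes, fathers, rfrac, rng),
            ]
        )
        zc = phenotype(genotypic_value(Population(child), arch), sE2, rng)
        midparent = (zp[mothers] + zp[fathers]) / 2
        slope = np.polyfit(midparent, zc, 1)[0]
        assert slope == pytest.approx(h2, abs=0.05)


class TestFitnessFunctions:
    def test_maximum_at_optimum(self):
        r = _regime()
        assert gaussian_fitness(np.array([r.z_opt]), r)[0] == 1.0

    def test_symmetry_around_optimum(self):
        r = _regime(a=3, b=1.8, mean=2.0, var=0.5)
        x = np.linspace(0.1, 5, 40)
        assert np.allclose(
            gaussian_fitness(r.z_opt + x, r), gaussian_fitness(r.z_opt - x, r)
        )

    def test_one_width_displacement(self):
        r = _regime()
        w = gaussian_fitness(np.array([r.z_opt + r.width]), r)[0]
        assert w == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_module_fitness_at_optimum_and_product_form(self):
        reg = FitnessRegime.module(a=1, b=3.6).anchor(np.zeros(20), np.ones(20))
        z = np.tile(reg.z_opt, (1, 1))
        assert module_fitness(z, reg)[0] == 1.0
        rng = np.random.default_rng(5)
        z = rng.normal(size=(7, 20))
        per_trait = np.exp(-((z - reg.z_opt) ** 2) / (4.0 * reg.Vs))
        assert np.allclose(module_fitness(z, reg), per_trait.prod(axis=1))

    def test_module_fitness_printed_convention(self):
        # one trait displaced by 2 sqrt(Vs): exponent -(4 Vs)/(4 Vs) = -1
        reg = FitnessRegime.module(a=1, b=3.6).anchor(np.zeros(20), np.ones(20))
        z = np.tile(reg.z_opt, (1, 1)).astype(float)
        z[0, 3] += 2 * np.sqrt(reg.Vs[3])
        assert module_fitness(z, reg)[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_module_fitness_standard_convention(self):
        reg = FitnessRegime.module(
            a=1, b=3.6, fitness_exponent_convention="standard_gaussian"
        ).anchor(np.zeros(20), np.ones(20))
        z = np.tile(reg.z_opt, (1, 1)).astype(float)
        z[0, 0] += reg.Vs[0]  # displaced by "one SD" under this reading
        assert module_fitness(z, reg)[0] == pytest.approx(np.exp(-0.5), rel=1e-12)


class TestNextGeneration:
    def test_population_size_preserved(self):
        rng = np.random.default_rng(6)
        pop = Population((rng.random((2, 37, 4)) < 0.5).astype(np.uint8))
        out = next_generation(pop, None, np.full(3, 0.5), seed=7)
        assert out.size == 37 and out.generation == pop.generation + 1

    def test_all_zero_fitness_raises(self):
        pop = Population(np.zeros((2, 5, 1), dtype=np.uint8))
        with pytest.raises(ValueError, match="extinct"):
            next_generation(pop, np.zeros(5), np.empty(0), seed=8)

    def test_fitness_scaling_invariance(self):
        rng = np.random.default_rng(9)
        pop = Population((rng.random((2, 40, 6)) < 0.5).astype(np.uint8))
        w = rng.uniform(0.1, 1.0, 40)
        a = next_generation(pop, w, np.full(5, 0.1), seed=10)
        b = next_generation(pop, 17.3 * w, np.full(5, 0.1), seed=10)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_offspring_counts_match_binomial_wright_fisher(self):
        # one unlinked locus at frequency p: derived-allele count in the next
        # generation is Binomial(2N, p)
        N, p = 25, 0.4
        n_rep = 10_000
        rng = np.random.default_rng(11)
        k0 = int(round(2 * N * p))
        base = np.zeros(2 * N, dtype=np.uint8)
        base[:k0] = 1
        counts = np.empty(n_rep, dtype=int)
        for i in range(n_rep):
            haps = rng.permutation(base).reshape(2, N, 1)
            out = next_generation(Population(haps), None, np.empty(0), rng)
            counts[i] = int(out.haplotypes.sum())
        p0 = k0 / (2 * N)
        k = np.arange(2 * N + 1)
        expected = stats.binom.pmf(k, 2 * N, p0) * n_rep
        # pool tail bins so every expected count is >= 5
        order = np.argsort(expected)
        obs_binned, exp_binned = [], []
        acc_o = acc_e = 0.0
        for kk in k:
            acc_o += np.sum(counts == kk)
            acc_e += expected[kk]
            if acc_e >= 5:
                obs_binned.append(acc_o)
                exp_binned.append(acc_e)
                acc_o = acc_e = 0.0
        obs_binned[-1] += acc_o
        exp_binned[-1] += acc_e
        chi = stats.chisquare(obs_binned, f_exp=np.array(exp_binned) * (sum(obs_binned) / sum(exp_binned)))
        assert chi.pvalue > 0.01

    def test_mean_crossovers_equal_map_length(self):
        # parent = all-0 / all-1 haplotypes: phase switches in the gamete
        # count recombination events; their mean equals the map length for a
        # dense map
        morgans = 3.0
        L = 600
        gmap = aa.generate_genetic_map(L, n_chromosomes=1, model=("uniform", morgans))
        rfrac = gmap.recombination_fractions()
        haps = np.zeros((2, 1, L), dtype=np.uint8)
        haps[1] = 1
        rng = np.random.default_rng(12)
        n_gam = 20_000
        gam = meiosis(haps, np.zeros(n_gam, dtype=int), rfrac, rng)
        switches = np.abs(np.diff(gam.astype(int), axis=1)).sum(axis=1)
        # fine-map Haldane fractions sum to slightly below the Morgan length
        assert switches.mean() == pytest.approx(rfrac.sum(), rel=0.03)
        assert switches.mean() == pytest.approx(morgans, rel=0.05)


class TestEvolve:
    def test_single_generation_trajectory(self, panel):
        arch = aa.build_trait_architecture(panel, M=10, shape=2.5, seed=13)
        traj = evolve(panel, arch, FitnessRegime.neutral(), N=50, generations=1, seed=14)
        assert traj.generations.tolist() == [1]
        assert traj.F(1) == 1.0

    def test_seed_determinism(self, panel):
        arch = aa.build_trait_architecture(panel, M=10, shape=2.5, seed=15)
        kw = dict(N=60, generations=20, record=5, seed=16)
        t1 = evolve(panel, arch, FitnessRegime.single_trait(), **kw)
        t2 = evolve(panel, arch, FitnessRegime.single_trait(), **kw)
        assert np.array_equal(t1.pheno_var, t2.pheno_var)
        assert np.array_equal(t1.pheno_mean, t2.pheno_mean)

    def test_neutral_single_locus_drift_variance(self):
        # allele-frequency variance across replicates after t generations is
        # p(1-p)(1 - (1-1/2N)^t)
        panel1 = aa.generate_founder_haplotypes(
            200, 1, sfs=("uniform", 0.5, 0.5), seed=17
        )
        N, t_gen, reps = 50, 21, 1000
        arch = TraitArchitecture(loci=[0], effect=[1.0], h2=1.0)
        rng = np.random.default_rng(18)
        freqs = np.empty(reps)
        for i in range(reps):
            _, pop = evolve(
                panel1, arch, FitnessRegime.neutral(), N=N, generations=t_gen,
                seed=rng, return_population=True,
            )
            freqs[i] = pop.allele_freq()[0]
        # founding is one extra binomial sampling step from the panel, then
        # t-1 Wright--Fisher reproduction steps:
        # var = pq/(2N) + pq (1 - 1/2N) (1 - (1-1/2N)^(t-1))
        pbar = panel1.freq[0]
        pq = pbar * (1 - pbar)
        d = 1 - 1 / (2 * N)
        expected = pq / (2 * N) + pq * d * (1 - d ** (t_gen - 1))
        assert np.var(freqs) == pytest.approx(expected, rel=0.15)

    def test_selected_trait_reaches_optimum(self, panel):
        # mild shift, few loci: the trait mean attains the optimum by
        # generation 100 in most replicates
        rng = np.random.default_rng(19)
        hits = 0
        reps = 60
        for _ in range(reps):
            arch = aa.build_trait_architecture(panel, M=5, shape=2.5, seed=rng)
            traj = evolve(
                panel, arch, FitnessRegime.single_trait(a=1, b=3.6),
                N=300, generations=100, record=[1, 100], seed=rng,
            )
            sd_anc = np.sqrt(traj.meta["V_anc"])
            z_opt = traj.mean_at(1) + sd_anc
            hits += abs(traj.mean_at(100) - z_opt) <= 0.25 * sd_anc
        assert hits / reps > 0.5

    def test_module_evolution_returns_per_trait_trajectories(self, panel):
        mod = build_module_architecture(panel, n_traits=20, rho=0.5, fraction_causal=0.05, seed=20)
        trajs = evolve_module(
            panel, mod, FitnessRegime.module(a=1, b=3.6), N=100, generations=10,
            record=[1, 10], seed=21,
        )
        assert len(trajs) == 20
        for t in trajs:
            assert t.generations.tolist() == [1, 10]
            assert t.F(1) == 1.0

    def test_zero_variance_architecture_rejected(self):
        panel_mono = aa.generate_founder_haplotypes(
            20, 3, sfs=("uniform", 0.5, 0.5), seed=22
        )
        arch = TraitArchitecture(loci=[0], effect=[0.0], h2=0.5)
        with pytest.raises(ValueError, match="ancestral genetic variance"):
            evolve(panel_mono, arch, FitnessRegime.neutral(), N=30, generations=5, seed=23)
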