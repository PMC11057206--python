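import numpy as np
import pytest
from scipy import stats
from scipy.special import polygamma

from adaptarch.expression_analysis import (
    analyze_counts,
    compare_de_vs_nonde,
    cv_partition,
    de_call_standin,
    jackknife_ci,
    log_cpm,
    per_gene_variance_change,
    tmm_factors,
)
from adaptarch.synthetic_data import simulate_expression_counts


class TestTMM:
    def test_homogeneous_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.poisson(50, size=800)
        counts = np.tile(col[:, None], (1, 6))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(200, size=2000) + 1
        counts = np.column_stack([base, 2 * base, base, base])
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0, atol=0.01)

    def test_geometric_mean_exactly_one(self):
        cm = simulate_expression_counts(n_genes=500, seed=2)
        f = tmm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, rel=1e-12)

    def test_composition_bias_corrected(self):
        # library 2 spends half its reads on 20 huge genes: TMM factors must
        # rescale so the majority of genes compare correctly
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=1000) + 1
        lib2 = base.copy()
        lib2[:20] = base[:20] * 2000
        counts = np.column_stack([base, lib2, base])
        f = tmm_factors(counts)
        lcpm = log_cpm(counts, f, pseudocount=0.5)
        med_diff = np.median(lcpm[20:, 1] - lcpm[20:, 0])
        assert abs(med_diff) < 0.05

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            tmm_factors(np.array([[0, 1], [0, 2]]))


class TestLogCPM:
    def test_natural_log_scale(self):
        counts = np.array([[27], [10_000_000 - 27]])
        lc = log_cpm(counts, pseudocount=0.0, lib_sizes=np.array([1e7]))
        # natural log, not log2: ln(CPM) with CPM = 2.7
        assert lc[0, 0] == pytest.approx(np.log(2.7), rel=1e-12)
        assert lc[0, 0] != pytest.approx(np.log2(2.7), rel=1e-3)

    def test_count_one_in_megaread_library_is_zero(self):
        counts = np.array([[1], [999_999]])
        lc = log_cpm(counts, pseudocount=0.0)
        assert lc[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_depth_doubling_invariance(self):
        rng = np.random.default_rng(4)
        c = rng.poisson(30, size=(100, 1)) + 1
        a = log_cpm(c, pseudocount=0.0)
        b = log_cpm(2 * c, pseudocount=0.0)
        assert np.allclose(a, b)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(np.ones((3, 2), dtype=int), factors=np.array([1.0, 0.0]))


class TestPerGeneVarianceChange:
    def test_identical_populations_give_unit_f(self):
        rng = np.random.default_rng(5)
        block = rng.normal(size=(50, 10))
        lcpm = np.hstack([block, block])
        pops = np.array(["anc1"] * 10 + ["evo1"] * 10)
        gs = per_gene_variance_change(lcpm, pops, pairing=[("anc1", "evo1")])
        assert np.allclose(gs["F"], 1.0)

    def test_generator_variance_factor_recovered(self):
        # high expression suppresses the Poisson term, so the log-scale
        # variance ratio tracks trigamma(1/(v*phi)) / trigamma(1/phi)
        phi, v = 0.05, 0.84
        cm = simulate_expression_counts(
            n_genes=1500,
            design={"anc1": 150, "evo1": 150},
            de_fraction=0.0,
            variance_factor=v,
            dispersion_model=("constant", phi),
            batch_effect=("normal", 0.0),
            batches={"anc1": "lot1", "evo1": "lot1"},
            baseline_log_mean=(np.log(2000.0), 1.0),
            seed=6,
        )
        lcpm = log_cpm(cm, tmm_factors(cm))
        gs = per_gene_variance_change(lcpm, cm.populations, pairing=[("anc1", "evo1")])
        expected = polygamma(1, 1 / (v * phi)) / polygamma(1, 1 / phi)
        assert np.median(gs["F"]) == pytest.approx(expected, abs=0.03)
        assert np.median(gs["F"]) == pytest.approx(0.84, abs=0.05)

    def test_only_listed_pairs_are_contrasted(self, default_counts):
        lcpm = log_cpm(default_counts, tmm_factors(default_counts))
        gs = per_gene_variance_change(lcpm, default_counts.populations)
        assert set(gs["pair"]) == {"anc1:evo1", "anc2:evo2"}

    def test_zero_ancestral_variance_flagged(self):
        lcpm = np.array([[1.0, 1.0, 1.0, 2.0, 3.0, 4.0]])
        pops = np.array(["anc1"] * 3 + ["evo1"] * 3)
        gs = per_gene_variance_change(lcpm, pops, pairing=[("anc1", "evo1")])
        assert gs["flagged"].iloc[0]
        assert np.isnan(gs["F"].iloc[0])

    def test_ancestral_replicate_variances_correlate(self):
        # two reconstituted ancestral samples from one generator: per-gene
        # variance estimates agree strongly when dispersions are heterogeneous
        cm = simulate_expression_counts(
            n_genes=5000,
            design={"anc1": 20, "evo1": 20, "anc2": 20, "evo2": 20},
            dispersion_model=("lognormal", 0.05, 0.8),
            seed=7,
        )
        lcpm = log_cpm(cm, tmm_factors(cm))
        gs = per_gene_variance_change(lcpm, cm.populations)
        v1 = gs[gs["pair"] == "anc1:evo1"]["var_anc"]
        v2 = gs[gs["pair"] == "anc2:evo2"]["var_anc"]
        assert stats.spearmanr(v1, v2).statistic > 0.7

    def test_scaled_mean_shift_recovers_generator(self, default_counts):
        res = analyze_counts(default_counts)
        gs = res["gene_stats"]
        sub = gs[gs["pair"] == "anc1:evo1"]
        shifts = np.abs(sub["scaled_mean_shift"].to_numpy()[default_counts.de_label])
        assert np.median(shifts) == pytest.approx(1.0, abs=0.15)


class TestJackknife:
    def test_constant_vector_zero_width_at_zero(self):
        est, lo, hi = jackknife_ci(np.full(10, 3.3))
        assert est == lo == hi == 0.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        est, lo, hi = jackknife_ci(x)
        assert lo <= np.var(x, ddof=1) <= hi
        # bias-corrected estimate stays close to the plug-in variance
        assert est == pytest.approx(np.var(x, ddof=1), rel=0.1)

    def test_coverage_of_true_variance(self):
        rng = np.random.default_rng(9)
        true_var, n, reps = 2.0, 20, 1000
        hits = 0
        for _ in range(reps):
            x = rng.normal(scale=np.sqrt(true_var), size=n)
            _, lo, hi = jackknife_ci(x)
            hits += lo <= true_var <= hi
        assert hits / reps == pytest.approx(0.95, abs=0.03)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            jackknife_ci(np.ones(2))


class TestCVPartition:
    def test_partition_identity_holds_exactly(self, default_counts):
        cv = cv_partition(default_counts)
        ok = ~cv["flagged"]
        assert np.allclose(
            cv.loc[ok, "total_cv2"],
            cv.loc[ok, "technical_cv2"] + cv.loc[ok, "biological_cv2"],
        )

    def test_high_expression_is_biology_dominated(self):
        cm = simulate_expression_counts(
            n_genes=300,
            design={"anc1": 30},
            de_fraction=0.0,
            variance_factor=1.0,
            baseline_log_mean=(np.log(3e4), 0.2),
            seed=10,
        )
        cv = cv_partition(cm, shrink=0.0)
        high = cv["mean_count"] >= 1e4
        assert (cv.loc[high, "technical_cv2"] <= 1e-4).all()
        share = cv.loc[high, "technical_cv2"] / cv.loc[high, "total_cv2"]
        assert share.mean() < 0.1

    def test_known_dispersion_recovered(self):
        cm = simulate_expression_counts(
            n_genes=2000,
            design={"anc1": 50},
            de_fraction=0.0,
            variance_factor=1.0,
            dispersion_model=("constant", 0.04),
            batch_effect=("normal", 0.0),
            seed=11,
        )
        cv = cv_partition(cm)
        well_measured = cv["mean_count"] > 20
        med = np.median(cv.loc[well_measured, "biological_cv2"])
        assert abs(med - 0.04) / 0.04 < 0.25

    def test_technical_share_decreases_with_sample_size(self):
        cm = simulate_expression_counts(
            n_genes=1500, design={"anc1": 50}, de_fraction=0.0,
            variance_factor=1.0, seed=12,
        )
        shares = []
        for n in (5, 10, 22, 50):
            cv = cv_partition(
                cm.counts[:, :n], populations=np.full(n, "anc1"), shrink=0.0
            )
            s = cv["technical_cv2"] / cv["total_cv2"]
            shares.append(float(np.nanmean(s.replace([np.inf], np.nan))))
        assert all(a > b for a, b in zip(shares, shares[1:]))

    def test_all_zero_gene_flagged(self):
        counts = np.array([[0, 0, 0], [5, 6, 7]])
        cv = cv_partition(counts, populations=np.array(["a"] * 3), shrink=0.0)
        assert bool(cv["flagged"].iloc[0]) and not bool(cv["flagged"].iloc[1])


class TestDEComparison:
    def test_identical_distributions_equal_medians(self):
        F = np.r_[np.full(50, 0.8), np.full(50, 0.8)]
        de = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        res = compare_de_vs_nonde(F, de)
        assert res["median_F_de"] == res["median_F_nonde"]
        assert not res["significant"]

    def test_null_calibration_random_labels(self):
        rng = np.random.default_rng(13)
        F = rng.lognormal(0.0, 0.3, size=600)
        hits, reps = 0, 400
        for _ in range(reps):
            de = np.zeros(600, bool)
            de[rng.choice(600, 120, replace=False)] = True
            hits += compare_de_vs_nonde(F, de)["significant"]
        rate = hits / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 4 * se

    def test_positive_control_variance_factor_contrast(self):
        n_genes = 1200
        rng = np.random.default_rng(14)
        de = np.zeros(n_genes, bool)
        de[rng.choice(n_genes, 300, replace=False)] = True
        vfac = np.where(de, 0.5, 1.0)
        cm = simulate_expression_counts(
            n_genes=n_genes, de_fraction=0.0, variance_factor=vfac, seed=15
        )
        lcpm = log_cpm(cm, tmm_factors(cm))
        gs = per_gene_variance_change(lcpm, cm.populations, pairing=[("anc1", "evo1")])
        res = compare_de_vs_nonde(gs["F"].to_numpy(), de)
        assert res["significant"]
        assert res["median_F_de"] < res["median_F_nonde"]


class TestDECallStandin:
    def test_null_data_yields_few_calls(self):
        cm = simulate_expression_counts(
            n_genes=1000, de_fraction=0.0, variance_factor=1.0, seed=16
        )
        lcpm = log_cpm(cm, tmm_factors(cm))
        calls = de_call_standin(lcpm, cm.populations)
        assert calls.mean() <= 0.02

    def test_one_sd_shift_mostly_recovered(self, default_counts):
        lcpm = log_cpm(default_counts, tmm_factors(default_counts))
        calls = de_call_standin(lcpm, default_counts.populations)
        truth = default_counts.de_label
        recall = (calls & truth).sum() / truth.sum()
        assert recall > 0.5

    def test_user_labels_override_exactly(self, default_counts):
        lcpm = log_cpm(default_counts, tmm_factors(default_counts))
        labels = np.zeros(default_counts.n_genes, bool)
        labels[::7] = True
        out = de_call_standin(lcpm, default_counts.populations, labels=labels)
        assert np.array_equal(out, labels)


class TestPipeline:
    def test_analyze_counts_null_and_shifted(self, default_counts):
        res = analyze_counts(default_counts)
        for pair, comp in res["comparisons"].items():
            assert 0 <= comp["t_p_value"] <= 1
        # the generator applies the same variance factor to DE and non-DE
        # genes, so variance changes are indistinguishable between classes
        assert any(not c["significant"] for c in res["comparisons"].values())
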