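import numpy as np
import pytest

from hrvscaling import (
    IndexLaw,
    PUBLISHED_GENDER_LAWS,
    PUBLISHED_LAWS,
    PopulationSpec,
    ScalingLaw,
    ancova_gender,
    anova_table,
    find_breakpoint,
    fit_power_law,
    prediction_interval,
    quadratic_comparison,
    synth_index_branches,
    synth_population,
)


class TestFitPowerLaw:
    def test_noiseless_power_law_exact(self):
        ages = np.geomspace(0.1, 90, 10)
        fit = fit_power_law(ages, 2.0 * ages**0.5)
        assert fit.prefactor == pytest.approx(2.0)
        assert fit.exponent == pytest.approx(0.5)
        assert fit.r == pytest.approx(1.0)
        assert fit.sd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_mean_rr_law_within_two_se(self):
        hits = 0
        for seed in range(20):
            pop = synth_population(
                PopulationSpec(
                    n_subjects=560, laws={"mean_rr": PUBLISHED_LAWS["mean_rr"]},
                    seed=seed,
                )
            )
            fit = fit_power_law(pop["age_years"], pop["value"])
            hits += abs(fit.exponent - 0.122) <= 2 * fit.exponent_err
            assert fit.p < 1e-4
        assert hits >= 17

    def test_bias_shrinks_with_n(self):
        errs = []
        for n in (50, 500, 5000):
            est = []
            for seed in range(10):
                rng = np.random.default_rng(seed)
                ages = 10 ** rng.uniform(-1, 2, n)
                vals = 5.0 * ages**0.3 * 10 ** rng.normal(0, 0.2, n)
                est.append(fit_power_law(ages, vals).exponent)
            errs.append(abs(np.mean(est) - 0.3))
        assert errs[2] < errs[0] + 0.02 and errs[2] < 0.01

    def test_identical_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct ages"):
            fit_power_law([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_power_law([1.0, 2.0, 3.0], [1.0, 0.0, 3.0])


class TestFindBreakpoint:
    def test_noiseless_break_recovered_at_nearest_grid_point(self):
        rng = np.random.default_rng(0)
        ages = 10 ** rng.uniform(np.log10(0.5), np.log10(60), 300)
        law = IndexLaw(ScalingLaw(10.0, 0.5), ScalingLaw(50.0, -0.3), 5.0)
        vals = law.mean_curve(ages)
        pw = find_breakpoint(ages, vals)
        grid = np.geomspace(2, 30, 25)
        assert pw.breakpoint == pytest.approx(grid[np.argmin(np.abs(grid - 5.0))])
        # exhaustive oracle: no other candidate has smaller pooled SSE
        for c in grid:
            L = ages <= c
            if L.sum() < 3 or (~L).sum() < 3:
                continue
            sse = fit_power_law(ages[L], vals[L]).sse + fit_power_law(
                ages[~L], vals[~L]
            ).sse
            assert pw.pooled_sse <= sse + 1e-12

    def test_single_power_law_reports_comparable_single_sse(self):
        rng = np.random.default_rng(1)
        ages = 10 ** rng.uniform(-1, 2, 200)
        vals = 5.0 * ages**0.3 * 10 ** rng.normal(0, 0.05, 200)
        pw = find_breakpoint(ages, vals)
        assert pw.pooled_sse <= pw.single_branch_sse
        assert pw.pooled_sse == pytest.approx(pw.single_branch_sse, rel=0.15)

    def test_two_branch_sd_rr_population_breaks_near_twelve(self):
        ages, vals = synth_index_branches(PUBLISHED_LAWS["sd_rr"], 177, 435, seed=0)
        pw = find_breakpoint(ages, vals)
        assert 9 <= pw.breakpoint <= 16
        assert pw.left.exponent == pytest.approx(0.26, abs=0.08)
        assert pw.right.exponent == pytest.approx(-0.20, abs=0.08)

    def test_order_and_duplication_invariance(self):
        ages, vals = synth_index_branches(PUBLISHED_LAWS["sd_rr"], 100, 200, seed=2)
        pw = find_breakpoint(ages, vals)
        perm = np.random.default_rng(0).permutation(ages.size)
        assert find_breakpoint(ages[perm], vals[perm]).breakpoint == pw.breakpoint
        dup = find_breakpoint(np.r_[ages, ages], np.r_[vals, vals])
        assert dup.breakpoint == pw.breakpoint

    def test_no_valid_candidate_rejected(self):
        with pytest.raises(ValueError, match="cut-off"):
            find_breakpoint([50.0, 60.0, 70.0, 80.0], [1.0, 2.0, 3.0, 4.0])


class TestAnova:
    def test_perfect_fit(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        t = anova_table(obs, obs, df_model=1)
        assert t.sse == 0.0
        assert t.msm == pytest.approx(t.sst / 1)

    def test_grand_mean_fit(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        t = anova_table(obs, np.full(4, obs.mean()), df_model=1)
        assert t.sse == pytest.approx(t.sst)
        assert t.msm == pytest.approx(0.0)

    def test_five_point_hand_example(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = np.array([1.1, 1.9, 3.0, 4.2, 4.8])
        t = anova_table(obs, fit, df_model=1)
        assert t.sse == pytest.approx(0.10)
        assert t.sst == pytest.approx(10.0)
        assert t.msm == pytest.approx(9.9)
        assert t.mse == pytest.approx(0.10 / 3)

    def test_identity_on_real_fits(self):
        ages, vals = synth_index_branches(PUBLISHED_LAWS["rmssd"], 116, 268, seed=3)
        fit = fit_power_law(ages, vals)
        t = anova_table(np.log10(vals), np.log10(fit.predict(ages)), df_model=1)
        ssm = t.msm * t.df_model
        assert t.sst == pytest.approx(t.sse + ssm, rel=1e-8)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal length"):
            anova_table([1.0, 2.0], [1.0], df_model=1)


class TestPredictionInterval:
    def test_zero_residual_fit_collapses(self):
        ages = np.geomspace(0.1, 90, 20)
        fit = fit_power_law(ages, 2.0 * ages**0.5)
        lo, hi = prediction_interval(fit, 10.0)
        assert lo == pytest.approx(2.0 * 10**0.5, rel=1e-6)
        assert hi == pytest.approx(2.0 * 10**0.5, rel=1e-6)

    def test_width_minimal_at_mean_log_age(self):
        pop = synth_population(
            PopulationSpec(n_subjects=300, laws={"mean_rr": PUBLISHED_LAWS["mean_rr"]},
                           seed=4)
        )
        fit = fit_power_law(pop["age_years"], pop["value"])
        xs = np.geomspace(0.1, 99, 41)
        widths = [
            np.log10(hi) - np.log10(lo)
            for lo, hi in (prediction_interval(fit, x) for x in xs)
        ]
        centre = 10**fit.log_age_mean
        i_min = int(np.argmin(widths))
        assert xs[i_min] == pytest.approx(centre, rel=0.2)
        assert all(np.diff(widths[i_min:]) > -1e-12)
        assert all(np.diff(widths[: i_min + 1]) < 1e-12)

    def test_nonpositive_age_rejected(self):
        ages = np.geomspace(0.1, 90, 20)
        fit = fit_power_law(ages, 2.0 * ages**0.5)
        with pytest.raises(ValueError):
            prediction_interval(fit, 0.0)


class TestAncovaGender:
    def test_distinct_sex_laws_detected(self):
        spec = PopulationSpec(
            n_subjects=271, laws={"sd_rr": PUBLISHED_LAWS["sd_rr"]},
            age_range=(12.0, 99.0), sex_laws=PUBLISHED_GENDER_LAWS, seed=5,
        )
        pop = synth_population(spec)
        g = ancova_gender(pop, "sd_rr")
        assert g.male.exponent == pytest.approx(-0.28, abs=2 * g.male.exponent_err)
        assert g.female.exponent == pytest.approx(-0.17, abs=2 * g.female.exponent_err)
        assert g.p_gender < 1e-3

    def test_identical_laws_give_null_p(self):
        ps = []
        law = {"sd_rr": PUBLISHED_LAWS["sd_rr"]}
        same = {"sd_rr": {"male": PUBLISHED_LAWS["sd_rr"].adult,
                          "female": PUBLISHED_LAWS["sd_rr"].adult}}
        for seed in range(40):
            pop = synth_population(
                PopulationSpec(n_subjects=200, laws=law, age_range=(12.0, 99.0),
                               sex_laws=same, seed=seed)
            )
            ps.append(ancova_gender(pop, "sd_rr").p_gender)
        assert np.mean(np.array(ps) > 0.05) >= 0.85

    def test_missing_sex_rejected(self):
        pop = synth_population(
            PopulationSpec(n_subjects=50, laws={"mean_rr": PUBLISHED_LAWS["mean_rr"]},
                           seed=6)
        )  # all sexes unknown
        with pytest.raises(ValueError, match="records above age"):
            ancova_gender(pop, "mean_rr")


class TestQuadraticComparison:
    def test_exact_quadratic_data(self):
        x = np.linspace(1, 10, 20)
        y = 2 + 3 * x - 0.5 * x**2
        t = quadratic_comparison(x, y, space="linear")
        assert t.sse == pytest.approx(0.0, abs=1e-16)

    def test_linear_data_has_tiny_quadratic_gain(self):
        x = np.linspace(1, 10, 20)
        y = 1.0 + 2.0 * x
        t = quadratic_comparison(x, y, space="linear")
        assert t.sse == pytest.approx(0.0, abs=1e-16)
        assert t.sst > 0

    def test_piecewise_beats_quadratic_on_two_branch_data(self):
        wins = 0
        for seed in range(15):
            ages, vals = synth_index_branches(
                PUBLISHED_LAWS["sd_rr"], 177, 435, seed=seed
            )
            pw = find_breakpoint(ages, vals)
            quad = quadratic_comparison(ages, vals, space="loglog")
            wins += pw.pooled_sse < quad.sse
        assert wins > 7

    def test_rank_deficiency(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            quadratic_comparison([2.0, 2.0, 3.0, 3.0], [1.0, 1.1, 2.0, 2.1])
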