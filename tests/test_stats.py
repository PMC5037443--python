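"""Group-comparison and longitudinal statistics against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from cartt2.errors import InsufficientDataError, UndefinedEffectError
from cartt2.stats import (
    ancova_adjusted_difference,
    change_from_summary,
    cohens_d,
    comparison_from_summary,
    crude_group_difference,
    layer_change_contrast,
    paired_change,
    significance_flag,
)
from cartt2.synthetic import (
    CellSpec,
    CohortSpec,
    CovariateEffects,
    GroupSpec,
    generate_synthetic_cohort,
)


def two_group_spec(mean_a, sd_a, n_a, mean_b, sd_b, n_b, seed, effects=CovariateEffects(),
                   age_a=(55.0, 7.5), age_b=(55.0, 7.5)):
    cells_a = {("Avg", "superficial"): CellSpec(mean_a, sd_a, 0.0, 1.0)}
    cells_b = {("Avg", "superficial"): CellSpec(mean_b, sd_b, 0.0, 1.0)}
    groups = {
        "healthy": GroupSpec(n=n_a, age_mean=age_a[0], age_sd=age_a[1], bmi_mean=24.4,
                             bmi_sd=3.1, female_fraction=0.6, cells=cells_a),
        "riskROA": GroupSpec(n=n_b, age_mean=age_b[0], age_sd=age_b[1], bmi_mean=28.0,
                             bmi_sd=5.0, female_fraction=0.5, cells=cells_b),
    }
    return CohortSpec(groups=groups, covariate_effects=effects, seed=seed)


class TestCrudeDifference:
    def test_identical_samples_null(self):
        a = [40.0, 41.0, 42.0, 43.0]
        res = crude_group_difference(a, a)
        assert res.mean_diff_ms == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert res.cohens_d == 0.0

    def test_closed_form_small_sample(self):
        """a=(1,2,3) vs b=(4,5,6): pooled SD 1, d -3, Student t with df 4."""
        res = crude_group_difference([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.mean_diff_ms == pytest.approx(-3.0)
        assert res.cohens_d == pytest.approx(-3.0)
        se = 1.0 * math.sqrt(1 / 3 + 1 / 3)
        t = -3.0 / se
        assert res.p_value == pytest.approx(2 * sps.t.sf(abs(t), 4), abs=1e-12)
        half = sps.t.ppf(0.975, 4) * se
        assert res.ci95 == pytest.approx((-3.0 - half, -3.0 + half), abs=1e-12)

    def test_matches_summary_form_exactly(self):
        rng = np.random.default_rng(8)
        a = rng.normal(45.4, 2.3, 89)
        b = rng.normal(48.1, 3.1, 28)
        full = crude_group_difference(a, b)
        summ = comparison_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert full == summ

    def test_unbiased_at_study_group_sizes(self):
        diffs = []
        for seed in range(300):
            df = generate_synthetic_cohort(two_group_spec(45.4, 2.3, 89, 48.1, 3.1, 28, seed))
            base = df[df["visit"] == "baseline"]
            a = base[base["group"] == "healthy"]["t2_ms"].to_numpy()
            b = base[base["group"] == "riskROA"]["t2_ms"].to_numpy()
            diffs.append(crude_group_difference(a, b).mean_diff_ms)
        diffs = np.asarray(diffs)
        se = math.sqrt(2.3**2 / 89 + 3.1**2 / 28) / math.sqrt(len(diffs))
        assert abs(diffs.mean() - (-2.7)) < 3.5 * se

    def test_welch_flag_changes_df(self):
        pooled = comparison_from_summary(45.4, 2.3, 89, 48.1, 3.1, 28)
        welch = comparison_from_summary(45.4, 2.3, 89, 48.1, 3.1, 28, equal_var=False)
        assert welch.ci95[0] < pooled.ci95[0]  # Welch wider here
        assert welch.mean_diff_ms == pooled.mean_diff_ms


class TestSummaryReproductions:
    def test_healthy_vs_risk_superficial(self):
        res = comparison_from_summary(45.4, 2.3, 89, 48.1, 3.1, 28)
        assert res.mean_diff_ms == pytest.approx(-2.7, abs=1e-12)
        assert round(res.ci95[0], 1) == -3.8
        assert round(res.ci95[1], 1) == -1.6
        assert abs(res.cohens_d) == pytest.approx(1.04, abs=0.05)
        assert res.significant_bonferroni

    def test_healthy_vs_risk_deep(self):
        res = comparison_from_summary(35.8, 1.8, 89, 37.3, 1.8, 28)
        assert res.mean_diff_ms == pytest.approx(-1.5, abs=1e-12)
        assert round(res.ci95[0], 1) == -2.3
        assert round(res.ci95[1], 1) == -0.7
        assert abs(res.cohens_d) == pytest.approx(0.81, abs=0.05)

    def test_equal_groups_symmetric(self):
        res = comparison_from_summary(40.0, 2.0, 30, 40.0, 2.0, 30)
        assert res.mean_diff_ms == 0.0
        assert res.cohens_d == 0.0
        assert res.ci95[0] == pytest.approx(-res.ci95[1])


class TestCohensD:
    def test_published_effect_size(self):
        assert cohens_d(48.0, 3.5, 32, 45.4, 2.3, 89) == pytest.approx(0.96, abs=0.05)

    def test_equal_means_zero(self):
        assert cohens_d(40.0, 2.0, 10, 40.0, 3.0, 12) == 0.0

    def test_diff_equal_to_pooled_sd_is_one(self):
        assert cohens_d(10.0, 2.0, 50, 8.0, 2.0, 50) == pytest.approx(1.0)

    def test_sign_antisymmetry_and_scale_invariance(self):
        d1 = cohens_d(48.0, 3.5, 32, 45.4, 2.3, 89)
        assert cohens_d(45.4, 2.3, 89, 48.0, 3.5, 32) == pytest.approx(-d1)
        assert cohens_d(480.0, 35.0, 32, 454.0, 23.0, 89) == pytest.approx(d1)

    def test_zero_pooled_sd_unequal_means_undefined(self):
        with pytest.raises(UndefinedEffectError):
            cohens_d(10.0, 0.0, 5, 8.0, 0.0, 5)


class TestPairedChange:
    def test_no_change_null(self):
        import pandas as pd

        rows = []
        for i, v in enumerate([40.0, 42.0, 44.0]):
            for visit in ("baseline", "year1"):
                rows.append({
                    "subject_id": f"s{i}", "group": "healthy", "age": 55.0,
                    "sex": "female", "bmi": 24.0, "visit": visit,
                    "plate": "Avg", "layer": "deep", "t2_ms": v,
                })
        df = pd.DataFrame(rows)
        res = paired_change(df, "healthy", "Avg", "deep")
        assert res.mean_change_ms == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_three_changes(self):
        """Changes (1,2,3): mean 2, SD 1, t = 2*sqrt(3), df 2."""
        from cartt2.stats import change_from_samples

        res = change_from_samples([1.0, 2.0, 3.0])
        assert res.mean_change_ms == pytest.approx(2.0)
        assert res.sd_change_ms == pytest.approx(1.0)
        t = 2.0 / (1.0 / math.sqrt(3))
        assert t == pytest.approx(3.464, abs=1e-3)
        assert res.p_value == pytest.approx(2 * sps.t.sf(t, 2), abs=1e-12)
        half = sps.t.ppf(0.975, 2) / math.sqrt(3)
        assert res.ci95 == pytest.approx((2 - half, 2 + half), abs=1e-12)

    def test_summary_mode_reproduces_printed_ci(self):
        res = change_from_summary(0.8, 1.3, 89)
        assert round(res.ci95[0], 1) == 0.5
        assert round(res.ci95[1], 1) == 1.1

    def test_insufficient_pairs_raise(self):
        import pandas as pd

        df = pd.DataFrame([
            {"subject_id": "s0", "group": "healthy", "age": 55.0, "sex": "male",
             "bmi": 24.0, "visit": "baseline", "plate": "Avg", "layer": "deep",
             "t2_ms": 40.0},
        ])
        with pytest.raises(InsufficientDataError):
            paired_change(df, "healthy", "Avg", "deep")


class TestLayerChangeContrast:
    def _cohort(self, seed, sup_change=(0.5, 1.4), deep_change=(0.8, 1.3), n=89):
        cells = {
            ("Avg", "superficial"): CellSpec(45.4, 2.3, *sup_change),
            ("Avg", "deep"): CellSpec(35.8, 1.8, *deep_change),
        }
        grp = GroupSpec(n=n, age_mean=55.0, age_sd=7.5, bmi_mean=24.4, bmi_sd=3.1,
                        female_fraction=0.6, cells=cells)
        return generate_synthetic_cohort(CohortSpec(groups={"healthy": grp}, seed=seed))

    def test_identical_layer_changes_null(self):
        df = self._cohort(0, sup_change=(0.5, 0.0), deep_change=(0.5, 0.0))
        res = layer_change_contrast(df, "healthy")
        assert res.mean_change_ms == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_sign_antisymmetry_under_label_swap(self):
        df = self._cohort(3)
        res = layer_change_contrast(df, "healthy")
        swapped = df.copy()
        swapped["layer"] = swapped["layer"].map(
            {"superficial": "deep", "deep": "superficial"}
        )
        res_sw = layer_change_contrast(swapped, "healthy")
        assert res_sw.mean_change_ms == pytest.approx(-res.mean_change_ms)
        assert res_sw.p_value == pytest.approx(res.p_value)

    def test_empirical_power_matches_analytic(self):
        """One-sample t power oracle: contrast mean 0.3, SD ~1.91 (two
        independent layer changes), n=89, alpha 0.05."""
        n, n_seeds = 89, 400
        sd_contrast = math.sqrt(1.4**2 + 1.3**2)
        ncp = 0.3 / (sd_contrast / math.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        analytic = sps.nct.sf(crit, n - 1, ncp) + sps.nct.cdf(-crit, n - 1, ncp)
        hits = 0
        for seed in range(n_seeds):
            df = self._cohort(seed, sup_change=(0.8, 1.4), deep_change=(0.5, 1.3), n=n)
            hits += layer_change_contrast(df, "healthy").p_value < 0.05
        assert hits / n_seeds == pytest.approx(analytic, abs=0.07)


class TestAncova:
    def test_orthogonal_covariates_equal_crude(self):
        """With the group indicator orthogonal to covariates by construction,
        the adjusted difference equals the crude difference exactly."""
        import pandas as pd

        rows = []
        # two groups with identical covariate patterns -> exact orthogonality
        for g, offset in (("healthy", 0.0), ("riskROA", 2.0)):
            for i, (age, bmi, sex) in enumerate(
                [(50, 22, "male"), (55, 27, "female"), (60, 24, "male"), (65, 31, "female")]
            ):
                rows.append({
                    "subject_id": f"{g}{i}", "group": g, "age": age, "sex": sex,
                    "bmi": bmi, "visit": "baseline", "plate": "Avg",
                    "layer": "deep", "t2_ms": 36.0 + offset + 0.1 * i,
                })
        df = pd.DataFrame(rows)
        from cartt2.stats import crude_difference_from_cohort

        adj = ancova_adjusted_difference(df, "Avg", "deep", ("riskROA", "healthy"))
        crude = crude_difference_from_cohort(df, "Avg", "deep", ("riskROA", "healthy"))
        assert adj.mean_diff_ms == pytest.approx(crude.mean_diff_ms, abs=1e-9)

    def test_rank_deficiency_reported(self):
        import pandas as pd

        rows = []
        for g in ("healthy", "riskROA"):
            for i in range(6):
                rows.append({
                    "subject_id": f"{g}{i}", "group": g, "age": 50.0, "sex": "male",
                    "bmi": 25.0, "visit": "baseline", "plate": "Avg",
                    "layer": "deep", "t2_ms": 36.0 + i,
                })
        df = pd.DataFrame(rows)
        with pytest.raises(Exception, match="rank-deficient"):
            ancova_adjusted_difference(df, "Avg", "deep", ("riskROA", "healthy"))

    def test_adjustment_removes_age_confounding(self):
        """Injected age effect + group age gap biases the crude contrast; the
        ANCOVA recovers the generator's true group effect."""
        effects = CovariateEffects(age=0.4, age_ref=57.0)
        true_effect = 45.4 - 48.1
        crude_err, adj_err = [], []
        for seed in range(60):
            spec = two_group_spec(
                45.4, 2.3, 89, 48.1, 3.1, 28, seed, effects=effects,
                age_a=(55.0, 7.5), age_b=(61.1, 9.4),
            )
            df = generate_synthetic_cohort(spec)
            from cartt2.stats import crude_difference_from_cohort

            crude = crude_difference_from_cohort(
                df, "Avg", "superficial", ("healthy", "riskROA")
            )
            adj = ancova_adjusted_difference(
                df, "Avg", "superficial", ("healthy", "riskROA")
            )
            crude_err.append(crude.mean_diff_ms - true_effect)
            adj_err.append(adj.mean_diff_ms - true_effect)
        # crude contrast absorbs the age gap: bias ~ 0.3 * (55.0 - 61.1)
        assert np.mean(crude_err) < -1.0
        assert abs(np.mean(adj_err)) < 0.35


class TestSignificanceFlag:
    @pytest.mark.parametrize(
        "p,family,expected",
        [(0.006, 6, True), (0.011, 6, False), (0.05, 1, False), (0.009, 6, False),
         (0.008, 6, True), (0.049, 1, True)],
    )
    def test_bonferroni_threshold(self, p, family, expected):
        assert significance_flag(p, family) is expected
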