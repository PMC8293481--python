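"""Partial Spearman engine: ranks, precision-matrix estimate vs the
residualization oracle, significance tiers, interactions, stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import residualized_partial_spearman
from mtlmorph import (
    AnalysisSpec,
    CohortSimSpec,
    correlation_matrix,
    interaction_test,
    partial_spearman,
    rank_transform,
    simulate_cohort,
    stratified_matrix,
    tier,
)
from mtlmorph.cohort import apply_subset
from mtlmorph.stats import encode_covariates, matrix_to_wide


class TestRankTransform:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((3, 1, 2), (3, 1, 2)),
            ((1, 1, 2), (1.5, 1.5, 3)),
            ((0, 0.5, 0.5, 3), (1, 2.5, 2.5, 4)),
        ],
    )
    def test_average_ranks_on_ties(self, values, expected):
        np.testing.assert_allclose(rank_transform(values), expected)

    def test_missing_values_stay_missing(self):
        ranks = rank_transform([2.0, np.nan, 1.0])
        assert np.isnan(ranks[1])
        np.testing.assert_allclose(ranks[[0, 2]], [2, 1])

    def test_all_missing_is_an_error(self):
        with pytest.raises(ValueError, match="missing"):
            rank_transform([np.nan, np.nan])


class TestTiers:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.06, "a"), (0.10, ""), (0.5, "")],
    )
    def test_strict_thresholds(self, p, expected):
        assert tier(p) == expected


class TestPartialSpearman:
    def test_no_covariates_reduces_to_plain_spearman_with_ties(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, size=40).astype(float)  # heavy ties
        y = rng.integers(0, 6, size=40).astype(float)
        res = partial_spearman(x, y)
        rho, p = sps.spearmanr(x, y)
        assert res.estimate == pytest.approx(rho, abs=1e-12)
        assert res.p_two_sided == pytest.approx(p, rel=1e-6)

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_residualization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, k = rng.integers(15, 60), rng.integers(1, 4)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        z = rng.normal(size=(n, k)) + 0.3 * x[:, None]
        res = partial_spearman(x, y, z)
        r_oracle, p_oracle = residualized_partial_spearman(x, y, z)
        assert res.estimate == pytest.approx(r_oracle, abs=1e-10)
        assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-10)

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"x": rng.normal(size=80), "z1": rng.normal(size=80), "z2": rng.normal(size=80)}
        )
        df["y"] = 0.4 * df.x + 0.3 * df.z1 + rng.normal(size=80)
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"], method="spearman")
        res = partial_spearman(df.x, df.y, df[["z1", "z2"]])
        assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p_two_sided == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        y = rng.normal(size=50) + 0.5 * x
        z = rng.normal(size=50)
        base = partial_spearman(x, y, z).estimate
        assert partial_spearman(np.exp(x), y, z).estimate == pytest.approx(base, abs=1e-12)
        assert partial_spearman(x, y**3, z).estimate == pytest.approx(base, abs=1e-12)

    def test_symmetric_in_x_and_y(self):
        rng = np.random.default_rng(6)
        x, y, z = rng.normal(size=(3, 40))
        a = partial_spearman(x, y, z)
        b = partial_spearman(y, x, z)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)

    def test_monotone_function_gives_estimate_one(self):
        x = np.arange(20, dtype=float)
        y = np.exp(x / 5)
        z = np.random.default_rng(1).normal(size=20)
        with pytest.warns(UserWarning, match="smallest positive"):
            res = partial_spearman(x, y, z)
        assert res.estimate == pytest.approx(1.0)
        assert 0 < res.p_two_sided < 1e-200

    def test_missing_values_reduce_n(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        x[:5] = np.nan
        res = partial_spearman(x, y)
        assert res.n == 25

    def test_collinear_covariates_are_an_error(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=(2, 30))
        z = rng.normal(size=30)
        with pytest.raises(ValueError):
            partial_spearman(x, y, np.column_stack([z, z]), covariate_names=["z", "z_copy"])

    def test_too_few_complete_cases_is_an_error(self):
        with pytest.raises(ValueError, match="complete cases"):
            partial_spearman([1, 2, 3], [3, 2, 1], [[1], [2], [3]])

    def test_trivariate_normal_matches_pearson_partial_value(self):
        # exchangeable correlation 0.5: partial corr = (0.5 - 0.25)/(1 - 0.25)
        rng = np.random.default_rng(12)
        cov = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        data = rng.multivariate_normal(np.zeros(3), cov, size=5000)
        res = partial_spearman(data[:, 0], data[:, 1], data[:, 2:])
        assert res.estimate == pytest.approx(1 / 3, abs=0.05)


class TestCorrelationMatrix:
    def test_cell_sample_sizes_match_complete_case_counts(self, default_cohort):
        spec = AnalysisSpec(conditioning="covariates_plus_other_pathologies")
        results = correlation_matrix(default_cohort, spec)
        for _, row in results.iterrows():
            cols = [f"mtl_{row['exposure']}", f"thickness_{row['outcome']}"] + row[
                "conditioning_set"
            ].split(";")
            expected_n = int(default_cohort[cols].notna().all(axis=1).sum())
            assert row["n"] == expected_n

    def test_covariates_only_mode_has_three_conditioners(self, default_cohort):
        spec = AnalysisSpec(exposures=("tau",), conditioning="covariates_only")
        results = correlation_matrix(default_cohort, spec)
        assert all(len(c.split(";")) == 3 for c in results["conditioning_set"])

    def test_subset_restricts_rows(self, default_cohort):
        spec = AnalysisSpec(exposures=("tau",), conditioning="covariates_only", subset="A_negative")
        results = correlation_matrix(default_cohort, spec)
        n_subset = len(apply_subset(default_cohort, "A_negative"))
        assert results["n"].max() <= n_subset

    def test_wide_layout_has_sample_size_row(self, default_cohort):
        results = correlation_matrix(default_cohort, AnalysisSpec())
        wide = matrix_to_wide(results)
        assert wide.index[0] == "Sample size"
        assert list(wide.columns) == list(dict.fromkeys(results["outcome"]))

    def test_per_location_doubles_the_outcomes(self, default_cohort):
        spec = AnalysisSpec(exposures=("tau",), per_location=True)
        results = correlation_matrix(default_cohort, spec)
        assert len(results) == 14


class TestInteractions:
    def test_constant_moderator_is_a_collinearity_error(self, default_cohort):
        table = default_cohort.copy()
        table["constant"] = 1.0
        with pytest.raises(ValueError, match="[Cc]ollinear|constant"):
            interaction_test(table, "thickness_BA35", "mtl_tau", "constant")

    def test_strong_simulated_interaction_beats_null_median(self):
        rng = np.random.default_rng(21)
        null_ps, effect_ps = [], []
        for rep in range(30):
            n = 58
            sex = rng.integers(0, 2, n).astype(float)
            x = rng.normal(size=n)
            age = rng.normal(70, 8, n)
            hemi = rng.integers(0, 2, n).astype(float)
            noise = rng.normal(0, 0.5, n)
            base = pd.DataFrame(
                {"x": x, "sex_code": sex, "age": age, "hemisphere_code": hemi}
            )
            base["y_null"] = 2.5 - 0.2 * x + noise
            base["y_mod"] = 2.5 - 0.8 * x * sex + noise
            null_ps.append(
                interaction_test(base, "y_null", "x", "sex_code", ("age", "hemisphere_code")).p_two_sided
            )
            effect_ps.append(
                interaction_test(base, "y_mod", "x", "sex_code", ("age", "hemisphere_code")).p_two_sided
            )
        assert np.median(effect_ps) < np.median(null_ps)
        assert np.median(effect_ps) < 0.01

    def test_tau_tdp_interaction_runs_on_simulated_cohort(self, default_cohort):
        res = interaction_test(default_cohort, "thickness_BA35", "mtl_tau", "mtl_TDP43")
        assert 0 < res.p_two_sided <= 1
        assert res.n <= len(default_cohort)


class TestStratification:
    def test_sex_strata_drop_sex_from_conditioning(self, default_cohort):
        spec = AnalysisSpec(exposures=("tau",), conditioning="covariates_only")
        strata = stratified_matrix(default_cohort, spec, strata="sex")
        assert set(strata) == {"male", "female"}
        for results in strata.values():
            assert all("sex_code" not in c.split(";") for c in results["conditioning_set"])

    def test_stratum_ns_sum_to_cohort_n(self, default_cohort):
        spec = AnalysisSpec(exposures=("tau",), conditioning="covariates_only")
        strata = stratified_matrix(default_cohort, spec, strata="sex")
        total = sum(r["n"].max() for r in strata.values())
        # complete-case n can fall below the stratum size but never above
        assert total <= len(default_cohort)
        assert all(r["n"].max() >= 4 for r in strata.values())
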