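"""PCA retention, canonical discriminants, group comparisons, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cndclr import (
    COMPONENTS,
    GroupSizeError,
    ZeroVarianceError,
    canonical_discriminant,
    compare_groups,
    encode_design_matrix,
    generate_group,
    pca_screen,
    samples_to_clr,
    yield_correlations,
)
from conftest import calibration_config


def frame(rng, n, p, prefix="v"):
    return pd.DataFrame(rng.standard_normal((n, p)), columns=[f"{prefix}{i}" for i in range(p)])


def clr_const(values):
    return pd.DataFrame([{c: v for c, v in zip(COMPONENTS, values)}])


class TestPca:
    def test_eigenvalue_sum_equals_variable_count(self):
        X = frame(np.random.default_rng(0), 200, 7)
        fm = pca_screen(X)
        assert fm.eigenvalues.sum() == pytest.approx(7.0, rel=1e-9)
        assert np.all(np.diff(fm.eigenvalues) <= 1e-12)

    def test_two_variables_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        y = 0.6 * x + 0.8 * rng.standard_normal(500)
        X = pd.DataFrame({"a": x, "b": y})
        rho = np.corrcoef(x, y)[0, 1]
        fm = pca_screen(X)
        np.testing.assert_allclose(fm.eigenvalues, [1 + rho, 1 - rho], rtol=1e-9)

    def test_duplicated_variable_yields_zero_eigenvalue(self):
        X = frame(np.random.default_rng(2), 50, 3)
        X["dup"] = X["v0"]
        fm = pca_screen(X)
        assert fm.eigenvalues[-1] == pytest.approx(0.0, abs=1e-9)
        assert fm.loadings.shape == (4, 4)

    def test_constant_column_named_in_error(self):
        X = frame(np.random.default_rng(3), 30, 3)
        X["flat"] = 1.0
        with pytest.raises(ZeroVarianceError, match="flat"):
            pca_screen(X)

    def test_loadings_reconstruct_correlation_matrix(self):
        X = frame(np.random.default_rng(4), 100, 5)
        fm = pca_screen(X)
        L = fm.loadings.to_numpy()
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        np.testing.assert_allclose(L @ L.T, R, atol=1e-9)

    def test_eigenvalues_match_sklearn_cross_check(self):
        from sklearn.decomposition import PCA

        X = frame(np.random.default_rng(5), 120, 6)
        z = (X - X.mean()) / X.std(ddof=1)
        sk = PCA(n_components=6).fit(z.to_numpy())
        fm = pca_screen(X)
        np.testing.assert_allclose(fm.eigenvalues, sk.explained_variance_, rtol=1e-8)

    def test_retention_and_flags(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal(300)
        X = pd.DataFrame(
            {
                "a": base + 0.1 * rng.standard_normal(300),
                "b": base + 0.1 * rng.standard_normal(300),
                "c": rng.standard_normal(300),
            }
        )
        fm = pca_screen(X)
        assert fm.retained == int((fm.eigenvalues > 1).sum()) >= 1
        assert fm.flagged.loc["a", "factor_1"]  # strong common factor

    def test_design_matrix_codes_by_first_appearance(self):
        df, _ = generate_group(calibration_config(n=20), 3)
        df.loc[:9, "region"] = "Zeta"
        df.loc[10:, "region"] = "Alpha"
        X = encode_design_matrix(df)
        assert X["region"].iloc[0] == 0.0  # Zeta appears first
        assert X["region"].iloc[-1] == 1.0
        assert X.attrs["categorical_codes"]["region"] == {"Zeta": 0, "Alpha": 1}
        assert "yield" in X.columns and set(COMPONENTS) <= set(X.columns)


class TestDiscriminant:
    def test_identical_groups_show_no_separation(self):
        X = frame(np.random.default_rng(7), 40, 4)
        both = pd.concat([X, X], ignore_index=True)
        groups = pd.Series(["a"] * 40 + ["b"] * 40)
        dm = canonical_discriminant(both, groups)
        np.testing.assert_allclose(dm.eigenvalues, 0.0, atol=1e-9)
        assert dm.wilks_overall == pytest.approx(1.0, abs=1e-9)

    def test_one_dimensional_closed_form(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([5.0, 6.0, 7.0])
        X = pd.DataFrame({"x": np.concatenate([a, b])})
        dm = canonical_discriminant(X, pd.Series(["a"] * 3 + ["b"] * 3))
        grand = X["x"].mean()
        between = 3 * (a.mean() - grand) ** 2 + 3 * (b.mean() - grand) ** 2
        within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        assert len(dm.eigenvalues) == 1
        assert dm.eigenvalues[0] == pytest.approx(between / within, rel=1e-9)
        assert dm.wilks_overall == pytest.approx(1 / (1 + between / within), rel=1e-9)

    def test_root_count_bounded_by_rank(self):
        rng = np.random.default_rng(8)
        X = frame(rng, 90, 5)
        groups = pd.Series(np.repeat(["a", "b", "c"], 30))
        dm = canonical_discriminant(X, groups)
        assert len(dm.eigenvalues) == 2  # min(groups-1, variables)
        assert np.all(np.diff(dm.cumulative_proportion) >= -1e-12)
        assert dm.cumulative_proportion[-1] == pytest.approx(1.0)
        assert 0 < dm.wilks_overall <= 1.0
        assert ((dm.wilks_per_variable > 0) & (dm.wilks_per_variable <= 1)).all()

    def test_separated_groups_have_small_wilks(self):
        rng = np.random.default_rng(9)
        a = frame(rng, 40, 3) - 3.0
        b = frame(rng, 40, 3) + 3.0
        dm = canonical_discriminant(
            pd.concat([a, b], ignore_index=True), pd.Series(["a"] * 40 + ["b"] * 40)
        )
        assert dm.wilks_overall < 0.1

    def test_single_group_rejected(self):
        X = frame(np.random.default_rng(10), 20, 3)
        with pytest.raises(GroupSizeError):
            canonical_discriminant(X, pd.Series(["only"] * 20))


class TestCompareGroups:
    def _clr(self, rng, n, shift=0.0):
        return pd.DataFrame(
            rng.standard_normal((n, 12)) + shift, columns=list(COMPONENTS)
        )

    def test_group_compared_with_itself(self):
        clr = self._clr(np.random.default_rng(11), 15)
        table = compare_groups(clr, clr.copy())
        np.testing.assert_allclose(table["t_value"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["p_value"], 1.0, atol=1e-12)
        assert table["similar"].all()

    def test_matches_pooled_variance_oracle(self):
        a = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in COMPONENTS})
        b = pd.DataFrame({c: [4.0, 5.0, 6.0] for c in COMPONENTS})
        table = compare_groups(a, b)
        # textbook pooled t: means 2 and 5, pooled variance 1, n=3 each
        t_expected = (2.0 - 5.0) / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        np.testing.assert_allclose(table["t_value"], t_expected, rtol=1e-12)
        np.testing.assert_allclose(table["p_value"], p_expected, rtol=1e-12)

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(12)
        a, b = self._clr(rng, 10), self._clr(rng, 12, shift=0.5)
        ab = compare_groups(a, b)
        ba = compare_groups(b, a)
        np.testing.assert_allclose(ba["t_value"], -ab["t_value"], rtol=1e-12)
        np.testing.assert_allclose(ba["p_value"], ab["p_value"], rtol=1e-12)

    def test_zero_pooled_variance_rejected(self):
        a = pd.DataFrame({c: [1.0, 1.0] for c in COMPONENTS})
        b = pd.DataFrame({c: [1.0, 1.0] for c in COMPONENTS})
        with pytest.raises(ZeroVarianceError):
            compare_groups(a, b)

    def test_null_p_values_are_uniform(self):
        # same-distribution groups: the p for one component over 500
        # simulations should pass a KS test against Uniform(0, 1)
        rng = np.random.default_rng(13)
        pvals = []
        for _ in range(500):
            t, p = stats.ttest_ind(rng.standard_normal(10), rng.standard_normal(10))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestYieldCorrelations:
    def test_scaled_copy_has_unit_correlation(self):
        df, _ = generate_group(calibration_config(n=30), 17)
        df["yield_t_ha"] = 2.0 * df["N"]
        table = yield_correlations(df)
        row = table[(table.stage == "concentration") & (table.variable == "N")]
        assert row["r"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert row["significant"].iloc[0]

    def test_negated_copy_has_minus_one(self):
        df, _ = generate_group(calibration_config(n=30), 18)
        df["yield_t_ha"] = 1000.0 - 3.0 * df["N"]
        table = yield_correlations(df)
        row = table[(table.stage == "concentration") & (table.variable == "N")]
        assert row["r"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_covariance_oracle_on_five_points(self):
        df, _ = generate_group(calibration_config(n=5), 19)
        table = yield_correlations(df)
        y = df["yield_t_ha"].to_numpy()
        for nut in ("N", "Zn"):
            x = df[nut].to_numpy()
            cov = ((x - x.mean()) * (y - y.mean())).sum() / 4
            r_oracle = cov / (x.std(ddof=1) * y.std(ddof=1))
            row = table[(table.stage == "concentration") & (table.variable == nut)]
            assert row["r"].iloc[0] == pytest.approx(r_oracle, abs=1e-12)

    def test_clr_block_includes_filler(self):
        df, _ = generate_group(calibration_config(n=20), 20)
        table = yield_correlations(df)
        clr_vars = set(table[table.stage == "clr"].variable)
        assert clr_vars == set(COMPONENTS)

    def test_too_few_samples_rejected(self):
        df, _ = generate_group(calibration_config(n=20), 21)
        with pytest.raises(GroupSizeError):
            yield_correlations(df.head(3))
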