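"""Multiple regression and factor correlation matrix."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from atrophymap.cohort_models import correlation_matrix, fit_multi_regression
from atrophymap.errors import CollinearityError, StatisticsError
from atrophymap.jacobian import normalize_to_two_years
from atrophymap.synthetic import CohortSpec, Ellipsoid, generate_cohort


class TestMultiRegression:
    def test_exact_linear_outcome_gives_unit_r_squared(self):
        x = np.arange(10.0)
        terms = pd.DataFrame({"x": x, "z": np.zeros(10)})
        # zero-variance second term would be collinear with the intercept
        terms["z"] = np.sin(x)
        fit = fit_multi_regression(3.0 * x - 1.0, terms)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_coefficients_match_normal_equations_oracle(self):
        """6-subject hand dataset: solve (X'X) b = X'y explicitly."""
        X = np.array(
            [
                [1, 0.2, 3.0],
                [1, -0.5, 2.0],
                [1, 1.1, 7.0],
                [1, 0.7, 5.0],
                [1, -1.3, 1.0],
                [1, 0.4, 6.0],
            ]
        )
        y = np.array([1.0, 0.2, 3.4, 2.2, -0.7, 2.9])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_multi_regression(y, pd.DataFrame({"a": X[:, 1], "b": X[:, 2]}))
        np.testing.assert_allclose(
            [fit.coefficients["const"], fit.coefficients["a"], fit.coefficients["b"]],
            oracle,
            atol=1e-10,
        )

    def test_null_r_squared_near_expectation(self):
        """Independent outcome: E[R^2] = k/(n-1); averaged over replicates."""
        k, n, reps = 3, 200, 40
        vals = []
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            terms = pd.DataFrame(rng.normal(size=(n, k)), columns=list("abc"))
            vals.append(fit_multi_regression(rng.normal(size=n), terms).r_squared)
        assert np.mean(vals) == pytest.approx(k / (n - 1), abs=0.005)

    def test_single_predictor_r_squared_equals_squared_correlation(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        fit = fit_multi_regression(y, pd.DataFrame({"x": x}))
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-10)

    def test_rank_deficiency_names_collinear_terms(self, rng):
        x = rng.normal(size=20)
        terms = pd.DataFrame({"x": x, "x2": 2.0 * x})
        with pytest.raises(CollinearityError, match="x"):
            fit_multi_regression(rng.normal(size=20), terms)

    def test_too_few_subjects_rejected(self, rng):
        terms = pd.DataFrame(rng.normal(size=(3, 2)), columns=["a", "b"])
        with pytest.raises(StatisticsError):
            fit_multi_regression(rng.normal(size=3), terms)

    def test_planted_cohort_predictor_beats_demographics(self):
        """On a planted-effect cohort the baseline-predictor p-value is the
        smallest term p-value in the demographic-adjusted regression."""
        spec = CohortSpec(
            n_subjects=60,
            grid_shape=(12, 12, 12),
            planted_region=Ellipsoid((6.0, 6.0, 6.0), (3.0, 3.0, 3.0)),
            effect_beta=0.03,
            noise_sigma=0.02,
            seed=2,
        )
        cohort = generate_cohort(spec)
        y = [
            normalize_to_two_years(m).values[cohort.truth_mask].mean()
            for m in cohort.logj_maps
        ]
        table = cohort.subject_table
        terms = table[["age", "gender", "education", "ethnicity", "fornix_fa"]]
        fit = fit_multi_regression(np.asarray(y), terms)
        p_fa = fit.p_values["fornix_fa"]
        others = [v for k, v in fit.p_values.items() if k not in ("const", "fornix_fa")]
        assert p_fa < min(others)


class TestCorrelationMatrix:
    def _factors(self, rng, n=40):
        a = rng.normal(size=n)
        return pd.DataFrame(
            {"a": a, "b": 0.6 * a + rng.normal(size=n), "c": rng.normal(size=n)}
        )

    def test_unit_diagonal_symmetry_and_bounds(self, rng):
        corr = correlation_matrix(self._factors(rng))
        arr = corr.to_numpy()
        np.testing.assert_array_equal(np.diag(arr), 1.0)
        np.testing.assert_allclose(arr, arr.T, atol=1e-15)
        assert np.all(np.abs(arr) <= 1.0 + 1e-12)

    def test_positive_semidefinite(self, rng):
        arr = correlation_matrix(self._factors(rng)).to_numpy()
        assert np.linalg.eigvalsh(arr).min() > -1e-10

    def test_factor_with_its_negation(self, rng):
        a = rng.normal(size=10)
        corr = correlation_matrix(pd.DataFrame({"a": a, "neg": -a, "c": a**2}))
        assert corr.loc["a", "neg"] == pytest.approx(-1.0)

    def test_matches_naive_covariance_loop_oracle(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 2.0, 4.0, 3.0, 5.0],
                "y": [2.2, 1.9, 3.1, 2.5, 3.4],
                "z": [0.1, -0.2, 0.4, 0.0, 0.3],
            }
        )
        corr = correlation_matrix(df)
        cols = list(df.columns)
        n = len(df)
        for ci in cols:
            for cj in cols:
                xi, xj = df[ci].to_numpy(), df[cj].to_numpy()
                sxy = sum(
                    (xi[t] - xi.mean()) * (xj[t] - xj.mean()) for t in range(n)
                )
                sxx = sum((v - xi.mean()) ** 2 for v in xi)
                syy = sum((v - xj.mean()) ** 2 for v in xj)
                assert corr.loc[ci, cj] == pytest.approx(
                    sxy / np.sqrt(sxx * syy), abs=1e-12
                )

    def test_invariant_to_positive_affine_rescaling(self, rng):
        df = self._factors(rng)
        scaled = df.copy()
        scaled["a"] = 100.0 * df["a"] + 7.0
        np.testing.assert_allclose(
            correlation_matrix(df).to_numpy(),
            correlation_matrix(scaled).to_numpy(),
            atol=1e-12,
        )

    def test_zero_variance_factor_named_in_error(self, rng):
        df = self._factors(rng)
        df["flat"] = 1.0
        with pytest.raises(StatisticsError, match="flat"):
            correlation_matrix(df)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(StatisticsError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, 0.1]}))
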