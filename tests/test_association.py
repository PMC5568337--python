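import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iopgrs import (
    anova_bonferroni,
    logistic_case_control,
    logistic_group_on_grs,
    standardized_linear_regression,
    unweighted_grs,
)
from iopgrs.association import POSTHOC_ALPHA, pairwise_t
from iopgrs.errors import CollinearityError, ContractError, InsufficientDataError
from iopgrs.scoring import ScoreVector


# -- standardized linear regression ------------------------------------------


def test_perfect_correlation_gives_unit_standardized_beta(rng):
    x = rng.normal(size=200)
    y = 3.0 * x - 7.0
    res = standardized_linear_regression(y, pd.DataFrame({"x": x}))
    assert res.predictor("x").beta_standardized == pytest.approx(1.0, abs=1e-9)
    assert res.predictor("x").p_value < 1e-100


def _normal_equations_oracle(y, X):
    """Direct matrix-solve OLS with raw SEs: the independent check."""
    design = np.column_stack([np.ones(len(X)), X.to_numpy()])
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta[1:], se[1:]


def test_ols_matches_normal_equations_on_fixture(rng):
    """Coefficients and raw SEs agree with a direct normal-equations solve on
    a fixed 20-row design."""
    X = pd.DataFrame(
        {
            "age": rng.normal(65, 10, 20),
            "male": rng.integers(0, 2, 20).astype(float),
            "grs": rng.integers(0, 19, 20).astype(float),
        }
    )
    y = 14 + 0.02 * X["age"] + 0.9 * X["male"] + 0.2 * X["grs"] + rng.normal(0, 1, 20)
    res = standardized_linear_regression(y.to_numpy(), X)
    beta_oracle, se_oracle = _normal_equations_oracle(y.to_numpy(), X)
    for j, name in enumerate(X.columns):
        assert res.predictor(name).beta_raw == pytest.approx(beta_oracle[j], abs=1e-8)
        assert res.predictor(name).se_raw == pytest.approx(se_oracle[j], abs=1e-8)


def test_standardized_beta_invariant_under_affine_rescaling(rng):
    X = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
    y = X["a"] - 0.5 * X["b"] + rng.normal(0, 0.7, 300)
    base = standardized_linear_regression(y.to_numpy(), X)
    X2 = pd.DataFrame({"a": 100 * X["a"] + 3, "b": 0.001 * X["b"] - 9})
    y2 = 5.5 * y + 40
    rescaled = standardized_linear_regression(y2.to_numpy(), X2)
    for name in ("a", "b"):
        assert rescaled.predictor(name).beta_standardized == pytest.approx(
            base.predictor(name).beta_standardized, abs=1e-10
        )


def test_null_predictor_type_one_error_near_nominal():
    """Independent outcome and predictor: |beta| small at large n, and the
    p < 0.05 rejection rate over replicates is near 5%."""
    rng = np.random.default_rng(404)
    big = standardized_linear_regression(
        rng.normal(size=10_000), pd.DataFrame({"x": rng.normal(size=10_000)})
    )
    assert abs(big.predictor("x").beta_standardized) < 0.05
    reps, hits = 1000, 0
    for _ in range(reps):
        y = rng.normal(size=120)
        x = rng.normal(size=120)
        r, p = stats.pearsonr(x, y)  # identical test; avoids 1000 OLS fits
        hits += p < 0.05
    # spot-check agreement between the OLS p-value and the correlation test
    res = standardized_linear_regression(y, pd.DataFrame({"x": x}))
    assert res.predictor("x").p_value == pytest.approx(p, abs=1e-12)
    assert 0.03 <= hits / reps <= 0.07


def test_constant_and_collinear_predictors_rejected(rng):
    y = rng.normal(size=50)
    with pytest.raises(CollinearityError, match="c"):
        standardized_linear_regression(
            y, pd.DataFrame({"x": rng.normal(size=50), "c": np.ones(50)})
        )
    x = rng.normal(size=50)
    with pytest.raises(CollinearityError) as err:
        standardized_linear_regression(
            y, pd.DataFrame({"x": x, "x2": 2 * x, "z": rng.normal(size=50)})
        )
    assert "x2" in err.value.columns


def test_too_few_rows_rejected(rng):
    with pytest.raises(InsufficientDataError):
        standardized_linear_regression(
            rng.normal(size=3), pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 4]})
        )


def test_row_order_does_not_change_results(rng):
    X = pd.DataFrame({"x": rng.normal(size=100), "z": rng.normal(size=100)})
    y = X["x"] + rng.normal(0, 1, 100)
    a = standardized_linear_regression(y.to_numpy(), X)
    perm = rng.permutation(100)
    b = standardized_linear_regression(y.to_numpy()[perm], X.iloc[perm])
    for name in ("x", "z"):
        assert a.predictor(name).beta_raw == pytest.approx(b.predictor(name).beta_raw, abs=1e-12)


def test_rows_with_missing_values_are_dropped_and_counted(rng):
    x = rng.normal(size=30)
    y = x + rng.normal(0, 0.1, 30)
    y[3] = np.nan
    x[7] = np.nan
    res = standardized_linear_regression(y, pd.DataFrame({"x": x}))
    assert res.n_used == 28


# -- ANOVA + Bonferroni ------------------------------------------------------


def test_two_group_f_equals_t_squared(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.4, 1, 35)
    f, _ = stats.f_oneway(a, b)
    t, _ = pairwise_t(a, b)
    assert f == pytest.approx(t**2, abs=1e-10)


def test_anova_requires_three_groups(rng):
    with pytest.raises(ContractError):
        anova_bonferroni(rng.normal(size=40), ["a"] * 20 + ["b"] * 20)


def test_separated_third_group_drives_all_significance(rng):
    scores = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
    groups = ["control"] * 50 + ["NTG"] * 50 + ["HTG"] * 50
    res = anova_bonferroni(scores, groups)
    assert res.p_value < 1e-6
    assert len(res.comparisons) == 3
    assert not res.comparison("NTG", "control").significant_at_bonferroni
    assert res.comparison("HTG", "control").significant_at_bonferroni
    assert res.comparison("HTG", "NTG").significant_at_bonferroni
    assert res.posthoc_alpha == pytest.approx(0.05 / 3)


def test_anova_type_one_error_near_nominal():
    rng = np.random.default_rng(777)
    reps, hits = 1000, 0
    for _ in range(reps):
        f, p = stats.f_oneway(*(rng.normal(size=30) for _ in range(3)))
        hits += p < 0.05
    # agreement spot-check between our stage and the library F on one draw
    samples = [rng.normal(size=30) for _ in range(3)]
    scores = np.concatenate(samples)
    groups = np.repeat(["a", "b", "c"], 30)
    ours = anova_bonferroni(scores, groups)
    f, p = stats.f_oneway(*samples)
    assert ours.f_statistic == pytest.approx(f, abs=1e-10)
    assert ours.p_value == pytest.approx(p, abs=1e-12)
    assert 0.03 <= hits / reps <= 0.07


def test_welch_posthoc_flag_changes_method(rng):
    scores = rng.normal(size=90)
    groups = np.repeat(["a", "b", "c"], 30)
    res = anova_bonferroni(scores, groups, welch=True)
    assert res.posthoc_method == "welch"


# -- logistic stage ----------------------------------------------------------


def test_logistic_null_grs_ci_covers_one_at_nominal_rate():
    """GRS permuted against labels: the 95% CI for the GRS odds ratio covers
    1.0 at close to the nominal rate."""
    rng = np.random.default_rng(2024)
    reps, covered = 300, 0
    for _ in range(reps):
        n = 400
        X = pd.DataFrame(
            {
                "age": rng.normal(65, 12, n),
                "male": rng.integers(0, 2, n).astype(float),
                "grs": rng.binomial(18, 0.48, n).astype(float),
            }
        )
        case = rng.random(n) < 0.5
        res = logistic_case_control(case, X)
        assert not res.separated
        p = res.predictor("grs")
        covered += p.ci_low <= 1.0 <= p.ci_high
    assert 0.92 <= covered / reps <= 0.985


def test_group_contrast_on_small_cohort(small_cohort, small_params):
    scores = unweighted_grs(small_cohort.genotypes, small_params.panel)
    res = logistic_group_on_grs(small_cohort.phenotypes, scores, "HTG")
    assert res.contrast == "HTG-vs-control"
    assert res.n_cases == 40 and res.n_controls == 40
    grs = res.predictor("grs")
    assert grs.ci_low <= grs.odds_ratio <= grs.ci_high
    with pytest.raises(ContractError):
        logistic_group_on_grs(small_cohort.phenotypes, scores, "POAG")


def test_threshold_defined_cases_raise_separation_flag(rng):
    n = 200
    grs = rng.binomial(18, 0.5, n).astype(float)
    X = pd.DataFrame(
        {"age": rng.normal(65, 10, n), "male": rng.integers(0, 2, n).astype(float), "grs": grs}
    )
    res = logistic_case_control(grs >= 9, X)
    assert res.separated
    assert res.predictors == []
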