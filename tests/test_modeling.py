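"""MLR core, LOO shortcut, stepwise and GA selection, diagnostics."""

import numpy as np
import pytest

from qsarscreen import (
    ConfigurationError,
    DescriptorTable,
    GAConfig,
    ModelingError,
    StepwiseConfig,
    SyntheticSpec,
    fit_mlr,
    ga_select,
    generate_dataset,
    loo_cv,
    outlier_flags,
    standardized_residuals,
    stepwise_select,
    vif,
)
from conftest import random_table


# ----------------------------------------------------------------------
# fit_mlr
# ----------------------------------------------------------------------

def test_noiseless_fit_is_exact():
    ds = generate_dataset(
        SyntheticSpec(n_compounds=25, n_descriptors=6, n_active=3, noise_sd=0.0,
                      true_coefficients=(1.0, -2.0, 0.5), intercept=3.0,
                      n_collinear_pairs=0, n_constant=0, seed=4)
    )
    m = fit_mlr(ds.table, ds.active_names)
    assert m.fit_stats.r2 == pytest.approx(1.0, abs=1e-12)
    assert m.fit_stats.se == pytest.approx(0.0, abs=1e-10)
    np.testing.assert_allclose(m.coefficients, [1.0, -2.0, 0.5], atol=1e-10)


def test_parameter_recovery_within_three_ses():
    ds = generate_dataset(SyntheticSpec(seed=1))  # n=46, 8 active, noise 0.3
    m = fit_mlr(ds.table, ds.active_names)
    assert np.all(np.abs(m.coefficients - ds.true_coefficients) <= 3 * m.coefficient_ses)


def test_pure_noise_column_has_negligible_r2(rng):
    n = 60
    t = DescriptorTable(
        [f"c{i}" for i in range(n)], ["x"], rng.standard_normal((n, 1)),
        activity=rng.standard_normal(n),
    )
    assert fit_mlr(t, ["x"]).fit_stats.r2 < 0.2


def test_fit_agrees_with_statsmodels(rng):
    """Independent least-squares route: statsmodels OLS on the same data."""
    import statsmodels.api as sm

    t = random_table(rng, 35, 6)
    m = fit_mlr(t, t.descriptor_names)
    ref = sm.OLS(t.activity, sm.add_constant(t.values)).fit()
    np.testing.assert_allclose(
        np.r_[m.intercept, m.coefficients], ref.params, atol=1e-8
    )
    np.testing.assert_allclose(
        np.r_[m.intercept_se, m.coefficient_ses], ref.bse, atol=1e-8
    )
    assert m.fit_stats.r2 == pytest.approx(ref.rsquared, abs=1e-10)
    assert m.fit_stats.r2_adj == pytest.approx(ref.rsquared_adj, abs=1e-10)
    assert m.fit_stats.f_stat == pytest.approx(ref.fvalue, abs=1e-8)


def test_rank_deficiency_names_dependent_columns(rng):
    X = rng.standard_normal((20, 3))
    X = np.column_stack([X, X[:, 0] + X[:, 1]])
    t = DescriptorTable(
        [f"c{i}" for i in range(20)], list("abcd"), X, activity=rng.standard_normal(20)
    )
    with pytest.raises(ModelingError, match="dependent"):
        fit_mlr(t, list("abcd"))


def test_too_few_observations_rejected(rng):
    t = random_table(rng, 5, 6)
    with pytest.raises(ConfigurationError):
        fit_mlr(t, t.descriptor_names)


def test_stats_invariants_on_random_fixtures(rng):
    for _ in range(10):
        t = random_table(rng, int(rng.integers(15, 50)), int(rng.integers(2, 8)))
        m = fit_mlr(t, t.descriptor_names)
        s = m.fit_stats
        assert s.r2_adj <= s.r2 + 1e-12
        assert s.q2_loo <= s.r2 + 1e-12
        assert s.press >= 0


# ----------------------------------------------------------------------
# leave-one-out
# ----------------------------------------------------------------------

def explicit_loo_press(t, names):
    """Oracle: n explicit refits, each leaving one compound out."""
    n = t.n_compounds
    press = 0.0
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        m = fit_mlr(t.select_rows(keep), names)
        yhat = m.predict_matrix(t.matrix(names)[[i]])[0]
        press += (t.activity[i] - yhat) ** 2
    return press


def test_perfect_model_has_unit_q2():
    ds = generate_dataset(
        SyntheticSpec(n_compounds=20, n_descriptors=4, n_active=2, noise_sd=0.0,
                      n_collinear_pairs=0, n_constant=0, seed=9)
    )
    q2, rmscv, press = loo_cv(ds.table, ds.active_names)
    assert q2 == pytest.approx(1.0, abs=1e-12)
    assert press == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("trial", range(20))
def test_hat_shortcut_equals_explicit_refits(rng, trial):
    n = int(rng.integers(15, 51))
    k = int(rng.integers(1, 11))
    t = random_table(rng, n, k)
    _, _, press = loo_cv(t, t.descriptor_names)
    assert press == pytest.approx(explicit_loo_press(t, t.descriptor_names), abs=1e-10)


def test_shuffled_activity_degrades_q2_below_r2(rng):
    t = random_table(rng, 46, 8)
    shuffled = DescriptorTable(
        t.compound_ids, t.descriptor_names, t.values,
        activity=rng.permutation(t.activity),
    )
    m = fit_mlr(shuffled, t.descriptor_names)
    assert m.fit_stats.q2_loo < m.fit_stats.r2


def test_hat_trace_is_k_plus_one(rng):
    from qsarscreen.modeling import _ols

    for _ in range(5):
        t = random_table(rng, int(rng.integers(12, 40)), int(rng.integers(1, 7)))
        X = np.column_stack([np.ones(t.n_compounds), t.values])
        _, _, hat, _ = _ols(X, t.activity)
        assert hat.sum() == pytest.approx(t.n_descriptors + 1, abs=1e-10)


# ----------------------------------------------------------------------
# stepwise
# ----------------------------------------------------------------------

def test_exact_predictor_forced_in(rng):
    x = rng.standard_normal(30)
    t = DescriptorTable(
        [f"c{i}" for i in range(30)], ["sig", "junk"],
        np.column_stack([x, rng.standard_normal(30)]), activity=x,
    )
    m = stepwise_select(t)
    assert "sig" in m.descriptor_names
    assert m.fit_stats.r2 == pytest.approx(1.0, abs=1e-12)


def test_constant_activity_selects_nothing(rng):
    t = DescriptorTable(
        [f"c{i}" for i in range(20)], ["a", "b"],
        rng.standard_normal((20, 2)), activity=np.full(20, 5.0),
    )
    m = stepwise_select(t)
    assert m.descriptor_names == []
    assert m.intercept == pytest.approx(5.0)


def test_stepwise_recovers_planted_majority():
    hits = 0
    for seed in range(10):
        ds = generate_dataset(
            SyntheticSpec(n_compounds=46, n_descriptors=30, n_active=8, noise_sd=0.2,
                          n_collinear_pairs=0, n_constant=0, seed=seed)
        )
        m = stepwise_select(ds.table)
        hits += len(set(m.descriptor_names) & set(ds.active_names)) > len(ds.active_names) / 2
    assert hits >= 9


# ----------------------------------------------------------------------
# GA
# ----------------------------------------------------------------------

def test_single_candidate_is_selected(rng):
    x = rng.standard_normal(25)
    t = DescriptorTable(
        [f"c{i}" for i in range(25)], ["only"], x[:, None],
        activity=2 * x + rng.normal(0, 0.1, 25),
    )
    m, _ = ga_select(t, GAConfig(population_size=10, max_generations=5, seed=0))
    assert m.descriptor_names == ["only"]


def test_ga_deterministic_for_fixed_seed(small_dataset):
    cfg = GAConfig(population_size=20, max_generations=15, seed=42)
    m1, h1 = ga_select(small_dataset.table, cfg)
    m2, h2 = ga_select(small_dataset.table, cfg)
    assert m1.descriptor_names == m2.descriptor_names
    assert h1 == h2


def test_ga_beats_or_matches_planted_subset(small_dataset):
    _, true_rmscv, _ = loo_cv(small_dataset.table, small_dataset.active_names)
    m, _ = ga_select(small_dataset.table, GAConfig(seed=11))
    assert m.fit_stats.rmscv <= true_rmscv + 0.05


def test_ga_respects_max_descriptor_bound(small_dataset):
    m, _ = ga_select(small_dataset.table, GAConfig(max_descriptors=3, seed=1))
    assert 1 <= m.k <= 3


def test_ga_not_much_worse_than_stepwise():
    """Sanity benchmark across seeds: GA RMScv within 10% of stepwise."""
    for seed in range(10):
        ds = generate_dataset(
            SyntheticSpec(n_compounds=40, n_descriptors=25, n_active=4, noise_sd=0.25,
                          n_collinear_pairs=0, n_constant=0, seed=seed)
        )
        sw = stepwise_select(ds.table)
        ga, _ = ga_select(ds.table, GAConfig(population_size=50, max_generations=60, seed=seed))
        assert ga.fit_stats.rmscv <= 1.1 * sw.fit_stats.rmscv


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------

def test_vif_orthogonal_columns_are_one():
    n = 8
    X = np.fft.fft(np.eye(n)).real[:, 1:4]  # mutually orthogonal, zero-mean
    t = DescriptorTable([f"c{i}" for i in range(n)], ["a", "b", "c"], X)
    np.testing.assert_allclose(vif(t, ["a", "b", "c"]), 1.0, atol=1e-8)


def test_vif_duplicate_column_infinite(rng):
    x = rng.standard_normal(15)
    t = DescriptorTable(
        [f"c{i}" for i in range(15)], ["a", "b"], np.column_stack([x, x])
    )
    assert np.all(np.isinf(vif(t, ["a", "b"])))


def test_vif_matches_auxiliary_regression_oracle(rng):
    import statsmodels.api as sm

    t = random_table(rng, 35, 8)
    got = vif(t, t.descriptor_names)
    for j in range(8):
        others = np.delete(t.values, j, axis=1)
        r2_j = sm.OLS(t.values[:, j], sm.add_constant(others)).fit().rsquared
        assert got[j] == pytest.approx(1.0 / (1.0 - r2_j), abs=1e-8)


def test_noiseless_residuals_are_zero():
    ds = generate_dataset(
        SyntheticSpec(n_compounds=20, n_descriptors=4, n_active=2, noise_sd=0.0,
                      n_collinear_pairs=0, n_constant=0, seed=3)
    )
    m = fit_mlr(ds.table, ds.active_names)
    r = standardized_residuals(m)
    np.testing.assert_allclose(r, 0.0, atol=1e-8)
    assert not outlier_flags(r).any()


def test_corrupted_compound_is_flagged(small_dataset):
    t = small_dataset.table
    bad = DescriptorTable(
        t.compound_ids, t.descriptor_names, t.values, activity=t.activity.copy()
    )
    bad.activity[7] += 5.0
    m = fit_mlr(bad, small_dataset.active_names)
    flags = outlier_flags(standardized_residuals(m))
    assert flags[7]


def test_outlier_flag_strict_at_threshold():
    r = np.array([2.5, -2.5, 2.5000001, -2.6, 0.0])
    np.testing.assert_array_equal(
        outlier_flags(r), [False, False, True, True, False]
    )
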