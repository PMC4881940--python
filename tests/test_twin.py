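"""Twin similarity estimators, ACE maximum likelihood, derived statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinstage import (
    CholeskyACEParams,
    MeanTrajectory,
    design,
    falconer_estimates,
    fit_ace_pairs,
    fit_cholesky_ace,
    fit_univariate_ace,
    icc_anova,
    intraclass_correlation,
    likelihood_ci,
    simulate_cohort,
    stage_specific_proportion,
    standardize_components,
)
from twinstage.simulate import simulate_pair_scores
from twinstage.twin import _TwoGroupObjective


def univariate_params(a2, c2, e2):
    return CholeskyACEParams(
        np.array([[np.sqrt(a2)]]), np.array([[np.sqrt(c2)]]), np.array([[np.sqrt(e2)]])
    )


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def test_identical_members_give_icc_one():
    rng = np.random.default_rng(0)
    v = rng.normal(size=30)
    icc, n, p = icc_anova(np.column_stack([v, v]))
    assert icc == pytest.approx(1.0)
    assert n == 30 and p < 1e-10


def test_independent_members_give_icc_near_zero():
    rng = np.random.default_rng(1)
    y = rng.normal(size=(10000, 2))
    icc, _, _ = icc_anova(y)
    assert abs(icc) < 2 / np.sqrt(10000)


def test_icc_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    u = rng.normal(size=40)
    y = u[:, None] + rng.normal(scale=0.8, size=(40, 2))
    icc, _, _ = icc_anova(y)
    long = pd.DataFrame(
        {
            "pair": np.repeat(np.arange(40), 2),
            "rater": np.tile([1, 2], 40),
            "score": y.ravel(),
        }
    )
    ref = pingouin.intraclass_corr(long, targets="pair", raters="rater", ratings="score")
    icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].iloc[0]
    assert icc == pytest.approx(icc1, abs=1e-6)


def test_cohort_icc_recovers_generating_correlations():
    """With a2=0.46, c2=0.09 the pair correlations are rMZ=0.55, rDZ=0.32."""
    p = univariate_params(0.46, 0.09, 0.45)
    rng = np.random.default_rng(3)
    y_mz = simulate_pair_scores(50000, p, "MZ", rng)
    y_dz = simulate_pair_scores(50000, p, "DZ", rng)
    r_mz, _, _ = icc_anova(y_mz[:, [0, 1]])
    r_dz, _, _ = icc_anova(y_dz[:, [0, 1]])
    assert abs(r_mz - 0.55) < 0.02
    assert abs(r_dz - 0.32) < 0.02


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match="2 complete pairs"):
        icc_anova(np.array([[1.0, 2.0]]))


# ---------------------------------------------------------------------------
# Falconer
# ---------------------------------------------------------------------------


def test_worked_falconer_values():
    f = falconer_estimates(0.55, 0.32)
    assert f.a2 == pytest.approx(0.46)
    assert f.c2 == pytest.approx(0.09)
    assert f.e2 == pytest.approx(0.45)
    assert not f.out_of_bounds


def test_equal_correlations_imply_no_heritability():
    f = falconer_estimates(0.4, 0.4)
    assert f.a2 == pytest.approx(0.0)
    assert f.c2 == pytest.approx(0.4)
    assert f.e2 == pytest.approx(0.6)


def test_pure_additive_limit():
    f = falconer_estimates(1.0, 0.5)
    assert (f.a2, f.c2, f.e2) == pytest.approx((1.0, 0.0, 0.0))


def test_out_of_bounds_flagged_not_clamped():
    f = falconer_estimates(0.6, 0.1)  # a2 = 1.0, c2 = -0.4
    assert f.out_of_bounds
    assert f.c2 == pytest.approx(-0.4)
    t = f.truncated()
    assert t.c2 == 0.0 and t.a2 + t.c2 + t.e2 == pytest.approx(1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    r_mz=st.floats(-1, 1, allow_nan=False),
    r_dz=st.floats(-1, 1, allow_nan=False),
)
def test_falconer_identity_exact(r_mz, r_dz):
    f = falconer_estimates(r_mz, r_dz)
    assert f.a2 + f.c2 + f.e2 == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# univariate ACE ML
# ---------------------------------------------------------------------------


def test_null_model_recovery_e_only():
    p = univariate_params(0.0, 0.0, 1.0)
    rng = np.random.default_rng(5)
    y_mz = simulate_pair_scores(10000, p, "MZ", rng)
    y_dz = simulate_pair_scores(10000, p, "DZ", rng)
    fit = fit_ace_pairs(y_mz[:, [0, 1]], y_dz[:, [0, 1]], n_stages=1, restarts=3)
    assert fit.components.total("A", 1) < 0.03
    assert fit.components.total("C", 1) < 0.03
    assert fit.components.total("E", 1) > 0.95


def test_loglik_at_optimum_beats_generating_parameters():
    p = univariate_params(0.48, 0.07, 0.45)
    rng = np.random.default_rng(6)
    y_mz = simulate_pair_scores(2000, p, "MZ", rng)[:, [0, 1]]
    y_dz = simulate_pair_scores(2000, p, "DZ", rng)[:, [0, 1]]
    fit = fit_ace_pairs(y_mz, y_dz, n_stages=1)
    obj = fit.objective
    theta_true = obj.theta_from_params(p)
    assert -0.5 * obj(theta_true) <= fit.loglik + 1e-6


def test_univariate_cohort_interface_and_min_pairs(small_cohort):
    fit = fit_univariate_ace(small_cohort, stage=1, outcome="wellbeing", restarts=2)
    assert fit.converged
    assert 0 < fit.components.total("A", 1) < 1
    with pytest.raises(ValueError, match="complete MZ pairs"):
        fit_univariate_ace(small_cohort, 1, "wellbeing", min_pairs=10**6)


# ---------------------------------------------------------------------------
# Cholesky ACE ML
# ---------------------------------------------------------------------------


def _first_column_params():
    """All additive-genetic variance transmitted from baseline."""
    la = np.zeros((4, 4))
    la[:, 0] = np.sqrt(0.5)
    lc = np.zeros((4, 4))
    le = np.sqrt(0.5) * np.eye(4)
    return CholeskyACEParams(la, lc, le)


def test_transmitted_only_genetics_recovers_zero_innovations():
    p = _first_column_params()
    rng = np.random.default_rng(7)
    y_mz = simulate_pair_scores(20000, p, "MZ", rng)
    y_dz = simulate_pair_scores(20000, p, "DZ", rng)
    fit = fit_ace_pairs(y_mz, y_dz, n_stages=4, restarts=3)
    for stage in (2, 3, 4):
        for factor in range(2, stage + 1):
            assert fit.components.contribution("A", factor, stage) < 0.02


def test_twin_label_permutation_leaves_loglik_unchanged(small_cohort):
    """Pairs are exchangeable: swapping twin 1 and twin 2 labels leaves the
    likelihood function (and hence the fitted optimum) unchanged."""
    from twinstage.cohort import pair_matrix

    fit = fit_cholesky_ace(small_cohort, "wellbeing", restarts=2)
    swapped = small_cohort.copy()
    swapped["twin_index"] = 3 - swapped["twin_index"]
    y_mz = pair_matrix(swapped, "wellbeing", "MZ")
    y_dz = pair_matrix(swapped, "wellbeing", "DZ")
    obj_sw = _TwoGroupObjective(y_mz, y_dz, 4, mode="fiml")
    # exact invariance of the likelihood at the fitted parameters
    assert obj_sw(fit.theta) == pytest.approx(fit.objective(fit.theta), abs=1e-8)
    fit_sw = fit_cholesky_ace(swapped, "wellbeing", restarts=2)
    assert fit.loglik == pytest.approx(fit_sw.loglik, abs=1e-3)


def test_single_stage_cholesky_equals_univariate_loglik():
    """Likelihood-equivalence oracle: the 1-stage triangular model and the
    univariate ACE model are the same model."""
    p = univariate_params(0.4, 0.1, 0.5)
    rng = np.random.default_rng(8)
    y_mz = simulate_pair_scores(3000, p, "MZ", rng)[:, [0, 1]]
    y_dz = simulate_pair_scores(3000, p, "DZ", rng)[:, [0, 1]]
    fit_a = fit_ace_pairs(y_mz, y_dz, n_stages=1, restarts=3, seed=1)
    fit_b = fit_ace_pairs(y_mz, y_dz, n_stages=1, restarts=3, seed=99)
    assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-6)


def test_fiml_uses_partial_pairs_and_matches_complete_on_full_data(wellbeing_params):
    coh = simulate_cohort(400, 500, wellbeing_params, MeanTrajectory(), seed=9)
    f_fiml = fit_cholesky_ace(coh, "wellbeing", mode="fiml", restarts=2)
    f_comp = fit_cholesky_ace(coh, "wellbeing", mode="complete", restarts=2)
    # same likelihood function on fully observed data
    assert f_fiml.objective(f_comp.theta) == pytest.approx(
        f_comp.objective(f_comp.theta), abs=1e-8
    )
    assert f_fiml.loglik == pytest.approx(f_comp.loglik, abs=1e-3)
    # with missing data, FIML keeps more pairs than complete-case
    from twinstage import apply_missingness

    miss = apply_missingness(coh, [0.05, 0.1, 0.1, 0.05], seed=9)
    f_m = fit_cholesky_ace(miss, "wellbeing", mode="fiml", restarts=2)
    assert sum(f_m.n_pairs.values()) > 0
    assert f_m.converged


# ---------------------------------------------------------------------------
# standardized components and derived statistics
# ---------------------------------------------------------------------------


def test_diagonal_unit_loadings_give_full_own_stage_contribution():
    p = CholeskyACEParams(np.zeros((4, 4)), np.zeros((4, 4)), np.eye(4))
    table = standardize_components(p)
    for s in range(1, 5):
        assert table.contribution("E", s, s) == pytest.approx(1.0)
        assert table.total("E", s) == pytest.approx(1.0)


def test_scaling_loadings_leaves_standardized_table_unchanged(wellbeing_params):
    t1 = standardize_components(wellbeing_params)
    scaled = CholeskyACEParams(
        3.7 * wellbeing_params.lambda_a,
        3.7 * wellbeing_params.lambda_c,
        3.7 * wellbeing_params.lambda_e,
    )
    t2 = standardize_components(scaled)
    pd.testing.assert_frame_equal(t1.point, t2.point)


def test_generating_table_round_trips_through_standardization(wellbeing_params):
    """Totals recovered from square-root loadings match the component table
    rows up to its two-decimal rounding."""
    table = standardize_components(wellbeing_params)
    for comp, key in (("A", "a"), ("C", "c"), ("E", "e")):
        expected = design.WELLBEING_COMPONENTS[key].sum(axis=1)
        for s in range(1, 5):
            # table proportions are normalized by total variance (≈1 ± rounding)
            assert abs(table.total(comp, s) - expected[s - 1]) < 0.02


def test_row_sums_are_one_for_fitted_parameters(small_cohort):
    fit = fit_cholesky_ace(small_cohort, "wellbeing", restarts=2)
    for s in range(1, 5):
        total = sum(fit.components.total(c, s) for c in ("A", "C", "E"))
        assert total == pytest.approx(1.0, abs=1e-8)


def test_wide_table_formats_ci_strings(wellbeing_params):
    table = standardize_components(wellbeing_params)
    table.ci[("A", "total", 1)] = (0.20, 0.64)
    wide = table.to_wide(decimals=2)
    assert wide.loc["A_total", "stage1"] == "0.48 (.20-.64)"
    assert wide.loc["A2", "stage1"] == ""  # triangular zero pattern


def test_stage_specific_proportion_worked_values():
    assert stage_specific_proportion([0.22, 0.06, 0.20], "E", 3) == pytest.approx(0.4167, abs=5e-4)
    assert stage_specific_proportion([0.16, 0.09, 0.38], "E", 3) == pytest.approx(0.6032, abs=5e-4)


def test_stage_one_proportion_is_always_unity(wellbeing_params):
    table = standardize_components(wellbeing_params)
    for comp in ("A", "C", "E"):
        assert stage_specific_proportion(table, comp, 1) == pytest.approx(1.0)


def test_zero_denominator_rejected():
    with pytest.raises(ValueError, match="zero"):
        stage_specific_proportion([0.0, 0.0, 0.0], "C", 3)


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def medium_univariate_fit():
    p = univariate_params(0.48, 0.07, 0.45)
    rng = np.random.default_rng(10)
    y_mz = simulate_pair_scores(375, p, "MZ", rng)[:, [0, 1]]
    y_dz = simulate_pair_scores(375, p, "DZ", rng)[:, [0, 1]]
    return fit_ace_pairs(y_mz, y_dz, n_stages=1, restarts=3)


def test_ci_contains_point_estimate(medium_univariate_fit):
    fit = medium_univariate_fit
    a_hat = fit.components.total("A", 1)
    lo, hi = likelihood_ci(fit, "A", "total", 1)
    assert lo <= a_hat <= hi
    assert 0.0 <= lo < hi <= 1.0


def test_boundary_quantity_gets_zero_lower_bound():
    """When the generating C variance is zero the profile lower bound sits
    on the admissible boundary and is reported as 0.00."""
    p = univariate_params(0.5, 0.0, 0.5)
    rng = np.random.default_rng(11)
    y_mz = simulate_pair_scores(2000, p, "MZ", rng)[:, [0, 1]]
    y_dz = simulate_pair_scores(2000, p, "DZ", rng)[:, [0, 1]]
    fit = fit_ace_pairs(y_mz, y_dz, n_stages=1, restarts=3)
    lo, hi = likelihood_ci(fit, "C", "total", 1)
    assert lo == 0.0
    assert hi < 0.2


def test_ci_width_shrinks_with_sample_size(medium_univariate_fit):
    """Profile CI width scales roughly as 1/sqrt(n): ~53x the pairs should
    shrink the A-total interval by clearly more than 4x."""
    lo_s, hi_s = likelihood_ci(medium_univariate_fit, "A", "total", 1)
    p = univariate_params(0.48, 0.07, 0.45)
    rng = np.random.default_rng(12)
    y_mz = simulate_pair_scores(20000, p, "MZ", rng)[:, [0, 1]]
    y_dz = simulate_pair_scores(20000, p, "DZ", rng)[:, [0, 1]]
    big = fit_ace_pairs(y_mz, y_dz, n_stages=1, restarts=2)
    lo_b, hi_b = likelihood_ci(big, "A", "total", 1)
    assert (hi_s - lo_s) / (hi_b - lo_b) > 4.0
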