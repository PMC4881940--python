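"""Cohort, item and missingness simulation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from twinstage import (
    CholeskyACEParams,
    MeanTrajectory,
    apply_missingness,
    design,
    pair_matrix,
    simulate_cohort,
    simulate_items,
    theoretical_pair_covariance,
)
from twinstage.preprocess import SCALES, score_items_frame

Z4 = np.zeros((4, 4))
E_ONLY = CholeskyACEParams(Z4, Z4, np.eye(4))
FLAT = MeanTrajectory()


def test_design_size_emits_750_individuals(small_cohort):
    individuals = small_cohort[["family_id", "twin_index"]].drop_duplicates()
    assert len(individuals) == 750
    assert len(small_cohort) == 750 * 4


def test_seed_determinism_byte_identical(wellbeing_params):
    kw = dict(params=wellbeing_params, trajectory=design.default_trajectory(), seed=5)
    a = simulate_cohort(30, 30, **kw)
    b = simulate_cohort(30, 30, **kw)
    pd.testing.assert_frame_equal(a, b)
    assert a.to_csv(index=False) == b.to_csv(index=False)


def test_e_only_scores_uncorrelated_across_twins():
    coh = simulate_cohort(4000, 1, E_ONLY, FLAT, seed=2)
    y = pair_matrix(coh, "wellbeing", "MZ")
    cross = np.corrcoef(y[:, 0], y[:, 4])[0, 1]
    assert abs(cross) < 2.5 / np.sqrt(4000)
    assert abs(y[:, 0].std() - 1.0) < 0.05


@pytest.mark.parametrize("n_pairs,tol", [(2000, 0.08), (32000, 0.02)])
def test_empirical_covariance_converges_to_theoretical(wellbeing_params, n_pairs, tol):
    """Entrywise agreement with the closed-form pair covariance improves
    roughly as 1/sqrt(n_pairs)."""
    coh = simulate_cohort(n_pairs, n_pairs, wellbeing_params, FLAT, seed=9)
    for zyg in ("MZ", "DZ"):
        y = pair_matrix(coh, "wellbeing", zyg)
        emp = np.cov(y, rowvar=False)
        theo = theoretical_pair_covariance(wellbeing_params, zyg)
        assert np.max(np.abs(emp - theo)) < tol


def test_mz_cross_correlations_dominate_dz(wellbeing_params):
    coh = simulate_cohort(20000, 20000, wellbeing_params, FLAT, seed=3)
    y_mz = pair_matrix(coh, "wellbeing", "MZ")
    y_dz = pair_matrix(coh, "wellbeing", "DZ")
    c_mz = np.corrcoef(y_mz, rowvar=False)[:4, 4:]
    c_dz = np.corrcoef(y_dz, rowvar=False)[:4, 4:]
    # Λa != 0 everywhere on the diagonal, so every cross-twin, cross-stage
    # correlation should be at least the DZ counterpart (up to MC noise)
    assert np.all(c_mz - c_dz > -0.02)
    assert np.all(np.diag(c_mz) > np.diag(c_dz))


def test_degenerate_params_rejected():
    p = CholeskyACEParams(Z4, Z4, np.diag([1.0, 0.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        simulate_cohort(5, 5, p, FLAT, seed=0)


def test_trajectory_and_covariate_effects_shift_means():
    traj = MeanTrajectory(baseline_mean=1.0, intervention_increment=0.5, sex_effect=0.4)
    coh = simulate_cohort(4000, 1, E_ONLY, traj, female_fraction=0.5, seed=8)
    means = coh.groupby("stage")["value"].mean()
    # expected: 1, 1, 1.5, 2.0 plus sex_effect * P(F)
    expect = np.array([1.0, 1.0, 1.5, 2.0]) + 0.4 * 0.5
    assert np.allclose(means.to_numpy(), expect, atol=0.05)
    by_sex = coh[coh["stage"] == 1].groupby("sex")["value"].mean()
    assert abs((by_sex["F"] - by_sex["M"]) - 0.4) < 0.06


# ---------------------------------------------------------------------------
# item simulation
# ---------------------------------------------------------------------------


def _latent_frame(values):
    n = len(values)
    return pd.DataFrame(
        {
            "family_id": [f"F{i//2:04d}" for i in range(n)],
            "zygosity": "MZ",
            "twin_index": [1 + i % 2 for i in range(n)],
            "sex": "F",
            "age": 16.5,
            "stage": 1,
            "outcome": "wellbeing",
            "value": values,
        }
    )


def test_extreme_latent_pins_items_at_scale_maximum():
    frame = _latent_frame(np.r_[np.full(50, 50.0), np.random.default_rng(0).normal(size=50)])
    items = simulate_items(frame, "BMSLSS", loading=1.0, seed=0)
    top = items[items["family_id"].isin(frame["family_id"][:50])]
    assert (top["value"] == SCALES["BMSLSS"].point_scale).all()


def test_noise_free_scoring_is_monotone_in_latent():
    """With loading 1 and no item noise, scoring then un-reversing recovers
    an exactly monotone (step) transform of the latent score."""
    rng = np.random.default_rng(1)
    frame = _latent_frame(rng.normal(size=400))
    items = simulate_items(frame, "SHS", loading=1.0, seed=1)
    scored = score_items_frame(items)
    merged = scored.merge(frame, on=["family_id", "twin_index"], suffixes=("_s", "_l"))
    ordered = merged.sort_values("value_l")["value_s"].to_numpy()
    assert np.all(np.diff(ordered) >= 0)
    # Spearman is near 1 up to discretization ties
    assert stats.spearmanr(merged["value_s"], merged["value_l"]).statistic > 0.9


def test_reverse_keyed_items_are_flipped():
    frame = _latent_frame(np.full(40, 50.0))  # far above every threshold
    items = simulate_items(frame, "SHS", loading=1.0, seed=0)
    rev = items[items["item"] == 4]["value"]
    fwd = items[items["item"] == 1]["value"]
    assert (fwd == 7).all() and (rev == 1).all()


def _threshold_model_correlation(loading, spec, gh_order=80):
    """Numerical-integration oracle for corr(scored scale, latent) under the
    equally spaced graded-threshold model."""
    thresholds = np.linspace(-2.5, 2.5, spec.point_scale - 1)
    s = np.sqrt(1 - loading**2)
    # probabilists' Gauss-Hermite: sum(weights) = sqrt(2*pi), so these
    # normalized weights integrate against the standard normal density
    nodes, weights = np.polynomial.hermite_e.hermegauss(gh_order)
    w = weights / np.sqrt(2 * np.pi)
    # E[item | z] and Var[item | z] at quadrature nodes
    pz = stats.norm.sf((thresholds[None, :] - loading * nodes[:, None]) / s)
    e_item = 1 + pz.sum(axis=1)
    # Var of a graded response: sum over threshold indicators' covariance
    var_item = np.zeros_like(nodes)
    for i in range(len(thresholds)):
        for j in range(len(thresholds)):
            pij = stats.norm.sf((max(thresholds[i], thresholds[j]) - loading * nodes) / s)
            var_item += pij - pz[:, i] * pz[:, j]
    mu = np.sum(w * e_item)
    cov_zy = np.sum(w * nodes * (e_item - mu))
    var_between = np.sum(w * (e_item - mu) ** 2)
    var_score = var_between + np.sum(w * var_item) / spec.n_items
    return cov_zy / np.sqrt(var_score)


def test_scored_scale_correlation_matches_integration_oracle():
    rng = np.random.default_rng(4)
    frame = _latent_frame(rng.normal(size=5000))
    items = simulate_items(frame, "SHS", loading=0.85, seed=4)
    scored = score_items_frame(items)
    merged = scored.merge(frame, on=["family_id", "twin_index"], suffixes=("_s", "_l"))
    r = np.corrcoef(merged["value_s"], merged["value_l"])[0, 1]
    expected = _threshold_model_correlation(0.85, SCALES["SHS"])
    assert abs(r - expected) < 0.05


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------


def test_zero_rates_leave_cohort_unchanged(small_cohort):
    out = apply_missingness(small_cohort, [0, 0, 0, 0], seed=1)
    pd.testing.assert_frame_equal(out, small_cohort)


def test_missingness_mask_is_seed_deterministic(small_cohort):
    a = apply_missingness(small_cohort, [0.1, 0.2, 0.1, 0.05], seed=7)
    b = apply_missingness(small_cohort, [0.1, 0.2, 0.1, 0.05], seed=7)
    pd.testing.assert_frame_equal(a, b)
    c = apply_missingness(small_cohort, [0.1, 0.2, 0.1, 0.05], seed=8)
    assert not a["value"].isna().equals(c["value"].isna())


def test_complete_pair_count_within_binomial_bounds(wellbeing_params):
    """Dropping individual-stage scores at rate 1 − 155/165 should leave a
    number of complete pairs at that stage consistent with a binomial with
    per-pair retention (155/165)²."""
    n_pairs = 165
    rate = 1.0 - 155.0 / 165.0
    coh = simulate_cohort(n_pairs, 1, wellbeing_params, FLAT, seed=12)
    out = apply_missingness(coh, [0.0, 0.0, rate, 0.0], seed=12)
    y = pair_matrix(out[out["zygosity"] == "MZ"], "wellbeing", "MZ")
    complete3 = (~np.isnan(y[:, [2, 6]]).any(axis=1)).sum()
    p_pair = (155 / 165) ** 2
    lo, hi = stats.binom.ppf([0.005, 0.995], n_pairs, p_pair)
    assert lo <= complete3 <= hi
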