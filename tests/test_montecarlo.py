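"""Monte Carlo observation-scale model: draw moments, study machinery,
null calibration, field geometry and the n_total sweep."""

import numpy as np
import pytest
from scipy import stats as sps

from synscale import (
    DSE_BASELINE,
    DSE_MIXTURE,
    ESP_BASELINE,
    ESP_MIXTURE,
    EfficacyDistribution,
    EnsembleConfig,
    FieldTopology,
    MixtureModel,
    Zone,
    draw_baseline,
    draw_post,
    field_pvalue_curve,
    hippocampal_field_topology,
    pvalue_curve,
    run_study,
    simulate_experiment,
    simulate_field_experiment,
    sweep_n_total,
    zone_fractions_from_radii,
)
from synscale.errors import ParameterError
from synscale.montecarlo import (
    _ensemble_replicates,
    _paired_t_pvalues,
    zone_area_fractions,
)
from synscale.stats import paired_t_test

# Closed-form mixture means from the printed single-synapse parameters
DSE_MEAN = 0.36 * 52.0 + 0.64 * 116.0  # 92.96
ESP_MEAN = 0.36 * 130.0 + 0.64 * 89.0  # 103.76


def test_draw_baseline_moments_and_degenerate_sigma():
    rng = np.random.default_rng(0)
    assert np.all(draw_baseline(10, EfficacyDistribution(100.0, 0.0), rng) == 100.0)
    x = draw_baseline(100_000, EfficacyDistribution(100.0, 61.0), np.random.default_rng(1))
    se = 61.0 / np.sqrt(x.size)
    assert abs(x.mean() - 100.0) < 4 * se
    with pytest.raises(ParameterError):
        draw_baseline(0, DSE_BASELINE)


def test_draws_reproducible_under_seed():
    a = draw_baseline(100, DSE_BASELINE, np.random.default_rng(5))
    b = draw_baseline(100, DSE_BASELINE, np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)
    va, fa = draw_post(100, DSE_MIXTURE, np.random.default_rng(5))
    vb, fb = draw_post(100, DSE_MIXTURE, np.random.default_rng(5))
    np.testing.assert_array_equal(va, vb)
    np.testing.assert_array_equal(fa, fb)


@pytest.mark.parametrize(
    "mixture, expected_mean",
    [(DSE_MIXTURE, DSE_MEAN), (ESP_MIXTURE, ESP_MEAN)],
)
def test_mixture_mean_matches_closed_form(mixture, expected_mean):
    values, flags = draw_post(100_000, mixture, np.random.default_rng(2))
    se = np.sqrt(mixture.variance / values.size)
    assert mixture.mean == pytest.approx(expected_mean)
    assert abs(values.mean() - expected_mean) < 4 * se
    f_se = np.sqrt(0.36 * 0.64 / values.size)
    assert abs(flags.mean() - 0.36) < 4 * f_se


def test_mixture_degenerate_fraction_zero_is_pure_unregulated():
    mix = MixtureModel(EfficacyDistribution(52, 16.3), EfficacyDistribution(116, 43), 0.0)
    values, flags = draw_post(10_000, mix, np.random.default_rng(3))
    assert not flags.any()
    assert abs(values.mean() - 116.0) < 4 * 43.0 / 100.0


def test_fixed_membership_uses_exact_count():
    values, flags = draw_post(25, DSE_MIXTURE, np.random.default_rng(4), membership="fixed")
    assert flags.sum() == round(0.36 * 25)


def test_ensemble_experiment_moments():
    # baseline_value ~ N(mu, sigma^2 / n_total); post mean -> mixture mean
    cfg = EnsembleConfig(n_total=12, tail="left", reps=10)
    rng = np.random.default_rng(6)
    exps = [simulate_experiment(cfg, DSE_BASELINE, DSE_MIXTURE, rng) for _ in range(4000)]
    base = np.array([e.baseline_value for e in exps])
    post = np.array([e.post_value for e in exps])
    var_th = 61.0**2 / 12
    assert abs(base.mean() - 100.0) < 4 * np.sqrt(var_th / base.size)
    assert base.var(ddof=1) == pytest.approx(var_th, rel=0.1)
    post_var_th = DSE_MIXTURE.variance / 12
    assert abs(post.mean() - DSE_MEAN) < 4 * np.sqrt(post_var_th / post.size)


def test_run_study_validates_and_matches_scalar_ttest():
    cfg = EnsembleConfig(n_total=12, tail="left", reps=10)
    with pytest.raises(ParameterError):
        run_study(1, cfg, DSE_BASELINE, DSE_MIXTURE)
    res = run_study(20, cfg, DSE_BASELINE, DSE_MIXTURE, np.random.default_rng(7))
    assert 0.0 <= res.p_value <= 1.0
    assert res.df == 19


def test_vectorized_pvalues_agree_with_scipy_paired_ttest():
    # dual route: closed-formula t (vectorized) vs scipy.stats.ttest_rel
    rng = np.random.default_rng(8)
    x = rng.normal(100, 10, (50, 9))
    y = rng.normal(95, 12, (50, 9))
    for tail, alt in [("left", "less"), ("right", "greater"), ("two_sided", "two-sided")]:
        ours = _paired_t_pvalues(x, y, tail)
        ref = np.array(
            [sps.ttest_rel(yi, xi, alternative=alt).pvalue for xi, yi in zip(x, y)]
        )
        np.testing.assert_allclose(ours, ref, rtol=1e-10)
        # and against the package's own paired_t_test on one row
        res = paired_t_test(x[0], y[0], tail)
        assert res.p_value == pytest.approx(ours[0])


@pytest.mark.parametrize("tail", ["left", "right", "two_sided"])
def test_null_calibration_rejection_rate(tail):
    # mixture == baseline: rejection fraction at alpha within 3 binomial SEs
    null_mix = MixtureModel(DSE_BASELINE, DSE_BASELINE, 0.36)
    cfg = EnsembleConfig(n_total=12, tail=tail, reps=4000)
    p = _ensemble_replicates(10, cfg, DSE_BASELINE, null_mix, np.random.default_rng(9))
    alpha = 0.05
    rate = (p < alpha).mean()
    se = np.sqrt(alpha * (1 - alpha) / p.size)
    assert abs(rate - alpha) < 3 * se


def test_null_scenario_never_reaches_significance():
    null_mix = MixtureModel(DSE_BASELINE, DSE_BASELINE, 0.36)
    cfg = EnsembleConfig(n_total=12, tail="left", reps=300)
    curve = pvalue_curve(cfg, DSE_BASELINE, null_mix, range(2, 41), np.random.default_rng(10))
    assert curve.n005 is None
    assert np.all(curve.aggregate_p > 0.3)  # mean p under the null is ~0.5


def test_dse_concealed_at_experimental_sample_size():
    # at the experimental n = 11, the aggregate p stays above 0.05
    cfg = EnsembleConfig(n_total=12, tail="left", reps=500)
    p = _ensemble_replicates(11, cfg, DSE_BASELINE, DSE_MIXTURE, np.random.default_rng(11))
    assert p.mean() > 0.05


def test_aggregate_p_decreases_with_sample_size():
    cfg = EnsembleConfig(n_total=12, tail="left", reps=500)
    curve = pvalue_curve(
        cfg, DSE_BASELINE, DSE_MIXTURE, [5, 20, 60, 120], np.random.default_rng(12)
    )
    assert np.all(np.diff(curve.aggregate_p) < 0)


def test_strong_effect_drives_p_to_zero():
    # regulated at 0 with vanishing spread, fraction 1: p -> 0 at modest n
    mix = MixtureModel(EfficacyDistribution(0.0, 1e-9), EfficacyDistribution(0.0, 1e-9), 1.0)
    cfg = EnsembleConfig(n_total=12, tail="left", reps=50)
    p = _ensemble_replicates(30, cfg, DSE_BASELINE, mix, np.random.default_rng(13))
    assert p.mean() < 1e-6


def test_zone_fractions_match_disc_geometry():
    assert zone_fractions_from_radii((60.0, 120.0, 180.0)) == (11, 33, 56)
    assert zone_fractions_from_radii((180.0,)) == (100,)
    exact = zone_area_fractions((60.0, 120.0, 180.0))
    np.testing.assert_allclose(exact, [100 / 9, 300 / 9, 500 / 9])
    assert exact.sum() == pytest.approx(100.0)
    with pytest.raises(ParameterError):
        zone_fractions_from_radii((120.0, 60.0))


def test_field_topology_cell_counts_and_validation():
    top = hippocampal_field_topology()
    assert tuple(z.n_cells for z in top.zones) == (11, 33, 56)
    assert top.zones[0].mixture is DSE_MIXTURE
    assert top.zones[1].mixture is ESP_MIXTURE
    assert top.zones[2].mixture is None
    with pytest.raises(ParameterError):
        FieldTopology((Zone(10, DSE_BASELINE),), n_cells=100)


def test_field_experiment_expectation_by_linearity():
    # E[post] = 0.11 m_DSE + 0.33 m_eSP + 0.56 x 100
    expected_post = 0.11 * DSE_MEAN + 0.33 * ESP_MEAN + 0.56 * 100.0
    cfg = EnsembleConfig(n_total=12, tail="two_sided", reps=10)
    rng = np.random.default_rng(14)
    top = hippocampal_field_topology()
    exps = [simulate_field_experiment(top, cfg, rng) for _ in range(800)]
    post = np.array([e.post_value for e in exps])
    base = np.array([e.baseline_value for e in exps])
    assert abs(post.mean() - expected_post) < 4 * post.std(ddof=1) / np.sqrt(post.size)
    assert abs(base.mean() - 100.0) < 4 * base.std(ddof=1) / np.sqrt(base.size)


def test_all_baseline_topology_is_null():
    top = FieldTopology((Zone(100, DSE_BASELINE, None),), n_cells=100)
    cfg = EnsembleConfig(n_total=12, tail="two_sided", reps=200)
    curve = field_pvalue_curve(top, cfg, range(2, 21), np.random.default_rng(15))
    assert curve.n005 is None


def test_sweep_n_total_monotone_between_extremes():
    # more synapses per ensemble -> smaller (or equal) n_0.05; a single
    # synapse needs far more experiments than the standard 12
    cfg = EnsembleConfig(n_total=12, tail="left", reps=300)
    df = sweep_n_total(
        [1, 12, 20], cfg, DSE_BASELINE, DSE_MIXTURE,
        n_grid=range(2, 501), stream=np.random.default_rng(16),
    )
    n1, n12, n20 = df["n005"].tolist()
    assert np.isnan(n1) or n1 > n12  # n_total=1 may not even reach p<0.05 by n=500
    assert n20 <= n12
    with pytest.raises(ParameterError):
        sweep_n_total([0], cfg, DSE_BASELINE, DSE_MIXTURE)


def test_invalid_grid_and_config_rejected():
    cfg = EnsembleConfig(n_total=12, tail="left", reps=10)
    with pytest.raises(ParameterError):
        pvalue_curve(cfg, DSE_BASELINE, DSE_MIXTURE, [])
    with pytest.raises(ParameterError):
        pvalue_curve(cfg, DSE_BASELINE, DSE_MIXTURE, [5, 3])
    with pytest.raises(ParameterError):
        EnsembleConfig(tail="sideways")
    with pytest.raises(ParameterError):
        EnsembleConfig(n_total=0)
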