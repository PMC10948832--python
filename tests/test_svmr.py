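import numpy as np
import pytest

from mrkit import (HarmonizedPair, cochran_q, egger, estimate_to_or, ivw,
                   leave_one_out, wald_ratio, weighted_median)
from mrkit.svmr import EstimationError, _weighted_median
from conftest import draw_pair


def _hp(g, se_g, G, se_G):
    g = np.atleast_1d(np.asarray(g, float))
    return HarmonizedPair([f"rs{i}" for i in range(g.size)], g,
                          np.broadcast_to(np.asarray(se_g, float), g.shape).copy(),
                          np.atleast_1d(np.asarray(G, float)),
                          np.broadcast_to(np.asarray(se_G, float), g.shape).copy())


def test_wald_ratio_closed_form():
    est = wald_ratio(_hp(0.10, 0.02, 0.05, 0.01))
    assert est.beta == pytest.approx(0.5)
    assert est.se == pytest.approx(0.1)
    est0 = wald_ratio(_hp(0.10, 0.02, 0.0, 0.01))
    assert est0.beta == 0.0 and est0.or_point == 1.0
    with pytest.raises(EstimationError):
        wald_ratio(_hp(0.0, 0.02, 0.05, 0.01))


def test_ivw_homogeneous_ratios():
    g = np.array([0.1, 0.2, 0.4])
    est = ivw(_hp(g, 0.01, 0.5 * g, 0.01))
    assert est.beta == pytest.approx(0.5)
    assert est.q == pytest.approx(0.0, abs=1e-20)
    assert est.q_p == pytest.approx(1.0)


def test_ivw_matches_origin_constrained_wls_oracle():
    """Independent oracle: statsmodels WLS through the origin."""
    import statsmodels.api as sm
    g = np.array([0.1, 0.2, 0.3])
    G = np.array([0.06, 0.10, 0.18])
    se = np.full(3, 0.01)
    est = ivw(_hp(g, 0.01, G, se), "fixed")
    fit = sm.WLS(G, g[:, None], weights=1 / se ** 2).fit()
    assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
    rng = np.random.default_rng(7)
    hp = draw_pair(rng, J=40, theta=0.3)
    est = ivw(hp, "fixed")
    fit = sm.WLS(hp.beta_out, hp.beta_exp[:, None],
                 weights=1 / hp.se_out ** 2).fit()
    assert est.beta == pytest.approx(fit.params[0], abs=1e-10)
    assert est.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale), abs=1e-10)


def test_ivw_single_snp_reduces_to_wald():
    hp = _hp(0.1, 0.02, 0.05, 0.01)
    est = ivw(hp)
    wald = wald_ratio(hp)
    assert est.method == "wald"
    assert est.beta == wald.beta and est.se == wald.se


def test_ivw_random_effects_never_deflates_se(rng):
    hp = draw_pair(rng, J=30, theta=0.2)
    assert ivw(hp, "multiplicative_random").se >= ivw(hp, "fixed").se - 1e-15


def test_exposure_rescaling_equivariance(rng):
    """gamma -> c*gamma divides beta by c and preserves the z-statistic."""
    hp = draw_pair(rng, J=25, theta=0.3)
    base = ivw(hp)
    c = 3.7
    scaled = HarmonizedPair(hp.snp_ids, c * hp.beta_exp, c * hp.se_exp,
                            hp.beta_out, hp.se_out)
    alt = ivw(scaled)
    assert alt.beta == pytest.approx(base.beta / c)
    assert alt.beta / alt.se == pytest.approx(base.beta / base.se)


def test_egger_exact_fit():
    g = np.array([0.1, 0.2, 0.3, 0.4])
    est = egger(_hp(g, 0.01, 0.02 + 0.5 * g, 0.01))
    assert est.beta == pytest.approx(0.5, abs=1e-12)
    assert est.egger_intercept == pytest.approx(0.02, abs=1e-12)
    assert est.q == pytest.approx(0.0, abs=1e-18)


def test_egger_matches_wls_oracle(rng):
    import statsmodels.api as sm
    hp = draw_pair(rng, J=30, theta=0.25, prop_invalid=0.3,
                   alpha_mean=0.03, alpha_sd=0.01)
    est = egger(hp)
    X = sm.add_constant(hp.beta_exp)
    fit = sm.WLS(hp.beta_out, X, weights=1 / hp.se_out ** 2).fit()
    assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
    assert est.beta == pytest.approx(fit.params[1], abs=1e-10)


def test_egger_slope_equals_ivw_when_intercept_zero():
    # construct data whose fitted Egger intercept is exactly zero
    g = np.array([1.0, 2.0, 3.0])
    G = np.array([1.0, 2.0, 3.0]) * 0.4
    est_e = egger(_hp(g, 0.01, G, 0.01))
    est_i = ivw(_hp(g, 0.01, G, 0.01))
    assert est_e.egger_intercept == pytest.approx(0.0, abs=1e-12)
    assert est_e.beta == pytest.approx(est_i.beta, abs=1e-12)


def test_egger_recovers_directional_pleiotropy():
    reps, alpha0 = 60, 0.03
    ints = []
    for s in range(reps):
        rng = np.random.default_rng(19_000 + s)
        hp = draw_pair(rng, J=50, theta=0.3, prop_invalid=1.0,
                       alpha_mean=alpha0, alpha_sd=0.005)
        ints.append(egger(hp).egger_intercept)
    ints = np.asarray(ints)
    mc_se = ints.std(ddof=1) / np.sqrt(reps)
    assert abs(ints.mean() - alpha0) < 2 * mc_se + 1e-9


def test_weighted_median_symmetric_and_interpolated():
    assert _weighted_median(np.array([0.1, 0.5, 0.9]),
                            np.ones(3)) == pytest.approx(0.5)
    # hand-computed CDF interpolation: p = cum(w) - w/2 hits 0.5 at the
    # central stratum exactly
    assert _weighted_median(np.array([0.0, 1.0, 2.0]),
                            np.array([0.49, 0.02, 0.49])) == pytest.approx(1.0)


def test_weighted_median_equals_plain_median_equal_weights(rng):
    theta = rng.normal(0.5, 0.2, 7)
    assert _weighted_median(theta, np.ones(7)) == pytest.approx(
        np.median(theta))


def test_weighted_median_estimator_runs_and_is_seed_stable(rng):
    hp = draw_pair(rng, J=20, theta=0.4)
    a = weighted_median(hp, n_boot=100, seed=3)
    b = weighted_median(hp, n_boot=100, seed=3)
    assert a.beta == b.beta and a.se == b.se
    assert a.se > 0


def test_leave_one_out_definition(rng):
    hp = draw_pair(rng, J=3, theta=0.3)
    loo = leave_one_out(hp, "fixed")
    for j in range(3):
        mask = np.ones(3, bool)
        mask[j] = False
        assert loo[j].beta == pytest.approx(ivw(hp.subset(mask), "fixed").beta)


def test_leave_one_out_isolates_planted_outlier():
    rng = np.random.default_rng(101)
    hp = draw_pair(rng, J=20, theta=0.5, se_out=0.02)
    hp.beta_out[4] += 1.0
    loo = leave_one_out(hp, "fixed")
    errors = [abs(e.beta - 0.5) for e in loo]
    assert int(np.argmin(errors)) == 4


def test_cochran_q_hand_expansion():
    g = np.array([0.1, 0.2])
    G = np.array([0.06, 0.09])
    se = np.array([0.01, 0.02])
    beta = 0.5
    q, q_df, q_p = cochran_q(_hp(g, 0.01, G, se), beta)
    expected = (0.06 - 0.05) ** 2 / 0.01 ** 2 + (0.09 - 0.10) ** 2 / 0.02 ** 2
    assert q == pytest.approx(expected)
    assert q_df == 1


def test_cochran_q_null_distribution():
    """Under homogeneity Q ~ chi-square(J-1) (Kolmogorov distance check)."""
    from scipy import stats
    J, reps = 10, 400
    qs = []
    for s in range(reps):
        rng = np.random.default_rng(50_000 + s)
        hp = draw_pair(rng, J=J, theta=0.3)
        qs.append(cochran_q(hp, ivw(hp, "fixed").beta)[0])
    d = stats.kstest(qs, stats.chi2(J - 1).cdf).statistic
    assert d < 0.08


def test_or_rendering_matches_printed_style():
    from mrkit import MREstimate
    est = MREstimate("ivw_re", 10, 0.0, 0.1, 1.0)
    o, lo, hi = estimate_to_or(est, 4)
    assert o == 1.0
    assert lo < 1.0 < hi
    # geometric-mean identity of Wald CIs on the OR scale
    assert np.sqrt(lo * hi) == pytest.approx(o, abs=5e-4)
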