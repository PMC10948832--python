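import numpy as np
import pytest

from mrkit import (LDMatrix, bma_diagnostics, bma_enumerate,
                   bma_rerun_without, joint_clump_for_bma)
from mrkit.svmr import EstimationError
from conftest import draw_multi, make_dataset


def test_single_exposure_has_one_model_with_pp_one(rng):
    ms = draw_multi(rng, J=30, theta=(0.4,))
    res = bma_enumerate(ms)
    assert len(res.models) == 1
    assert res.models["pp"].iloc[0] == pytest.approx(1.0)
    assert res.mip.iloc[0] == pytest.approx(1.0)


def test_pp_mip_mace_identities(rng):
    """Normalization and the marginal summation identities to 1e-10."""
    ms = draw_multi(rng, J=60, theta=(0.4, 0.0, -0.1), corr=0.3)
    res = bma_enumerate(ms, prior_inclusion=0.2)
    assert res.models["pp"].sum() == pytest.approx(1.0, abs=1e-10)
    assert ((res.mip >= -1e-12) & (res.mip <= 1 + 1e-12)).all()
    for k, name in enumerate(res.exposure_names):
        mip_k = sum(pp for subset, pp in zip(res.models["subset"],
                                             res.models["pp"])
                    if name in subset)
        assert res.mip[name] == pytest.approx(mip_k, abs=1e-10)
        mace_k = sum(pp * est[list(subset).index(name)]
                     for subset, pp, est in zip(res.models["subset"],
                                                res.models["pp"],
                                                res.models["estimates"])
                     if name in subset)
        assert res.mace[name] == pytest.approx(mace_k, abs=1e-10)


def test_large_g_limit_recovers_least_squares(rng):
    """g -> infinity: conditional effects converge to the WLS estimates."""
    ms = draw_multi(rng, J=50, theta=(0.4, -0.2))
    res = bma_enumerate(ms, g=1e8)
    full = [r for r in res.models.itertuples()
            if r.subset_idx == (0, 1)][0]
    y = ms.beta_out / ms.se_out
    X = ms.beta_exp / ms.se_out[:, None]
    wls = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(full.estimates, wls, atol=1e-4)


def test_signal_monotonicity_of_mip(rng):
    """Scaling the outcome toward exposure 1's column never lowers MIP[1]."""
    ms = draw_multi(rng, J=50, theta=(0.0, 0.0))
    mips = []
    for lam in (0.0, 0.3, 0.6, 1.0):
        ms2 = draw_multi(np.random.default_rng(0), J=50, theta=(0.0, 0.0))
        ms2.beta_exp = ms.beta_exp
        ms2.beta_out = (1 - lam) * ms.beta_out + lam * 0.5 * ms.beta_exp[:, 0]
        ms2.se_out = ms.se_out
        mips.append(bma_enumerate(ms2).mip.iloc[0])
    assert all(b >= a - 1e-12 for a, b in zip(mips, mips[1:]))


def test_ranking_recovery_one_causal_exposure():
    wins = 0
    reps = 50
    for s in range(reps):
        rng = np.random.default_rng(41_000 + s)
        ms = draw_multi(rng, J=60, theta=(0.5, 0.0), corr=0.2)
        res = bma_enumerate(ms)
        wins += res.ranking[0] == res.exposure_names[0]
    assert wins / reps >= 0.9


def test_null_favours_sparse_models_without_preferring_any_exposure():
    """Under the global null the posterior concentrates on small models
    (mean MIP below the prior's conditional inclusion rate) and treats the
    exchangeable exposures symmetrically."""
    reps, prior, K = 60, 0.1, 3
    per_exposure = []
    for s in range(reps):
        rng = np.random.default_rng(43_000 + s)
        ms = draw_multi(rng, J=60, theta=(0.0,) * K)
        per_exposure.append(bma_enumerate(ms, prior_inclusion=prior)
                            .mip.to_numpy())
    per_exposure = np.asarray(per_exposure)
    # prior inclusion conditional on a non-empty subset
    prior_cond = prior / (1 - (1 - prior) ** K)
    assert per_exposure.mean() < prior_cond
    means = per_exposure.mean(axis=0)
    mc_se = per_exposure.std(ddof=1) / np.sqrt(reps)
    assert np.ptp(means) < 4 * mc_se.max()


def test_diagnostics_exact_fit_flags_nothing(rng):
    ms = draw_multi(rng, J=30, theta=(0.4,))
    ms.beta_out = ms.beta_exp[:, 0] * 0.4     # exact single-exposure fit
    res = bma_enumerate(ms)
    diag = bma_diagnostics(ms, res, pp_threshold=0.0)
    assert diag.flagged_snps == []
    assert (diag.table["cook_distance"] < 1e-18).all()


def test_diagnostics_vacuous_threshold(rng):
    ms = draw_multi(rng, J=40, theta=(0.4, 0.0))
    res = bma_enumerate(ms)
    diag = bma_diagnostics(ms, res, pp_threshold=1.1)
    assert len(diag.table) == 0 and diag.flagged_snps == []


def test_diagnostics_flag_planted_high_leverage_outlier():
    rng = np.random.default_rng(47)
    ms = draw_multi(rng, J=40, theta=(0.4, 0.0), se_out=0.02)
    # high-leverage point: huge instrument effect, discrepant outcome
    ms.beta_exp[5, 0] = 0.8
    ms.beta_out[5] = 0.8 * 0.4 + 0.5
    res = bma_enumerate(ms)
    diag = bma_diagnostics(ms, res, pp_threshold=0.02)
    assert "rs5" in diag.flagged_snps


def test_rerun_without_empty_set_is_identity(rng):
    ms = draw_multi(rng, J=40, theta=(0.4, 0.0))
    a = bma_enumerate(ms)
    b = bma_rerun_without(ms, [])
    np.testing.assert_allclose(a.models["pp"], b.models["pp"], atol=1e-14)
    np.testing.assert_allclose(a.mip, b.mip, atol=1e-14)


def test_rerun_after_outlier_removal_keeps_or_improves_ranking():
    rng = np.random.default_rng(53)
    ms = draw_multi(rng, J=50, theta=(0.5, 0.0), se_out=0.02)
    ms.beta_exp[3, 0] = 0.7
    ms.beta_out[3] = -0.4          # adversarial outlier against exposure 1
    res = bma_enumerate(ms)
    diag = bma_diagnostics(ms, res, pp_threshold=0.02)
    assert diag.flagged_snps
    res2 = bma_rerun_without(ms, diag.flagged_snps)
    assert res2.mip[res2.exposure_names[0]] >= res.mip[res.exposure_names[0]] - 1e-9


def test_rerun_robust_to_removing_noninfluential_snps():
    rng = np.random.default_rng(59)
    ms = draw_multi(rng, J=60, theta=(0.5, 0.0), se_out=0.02)
    res = bma_enumerate(ms)
    drop = [f"rs{j}" for j in rng.choice(60, size=5, replace=False)]
    res2 = bma_rerun_without(ms, drop)
    assert np.max(np.abs(res2.mace.to_numpy() - res.mace.to_numpy())) < 0.1


def test_rerun_underidentified_is_fatal(rng):
    ms = draw_multi(rng, J=10, theta=(0.4, 0.0))
    with pytest.raises(EstimationError):
        bma_rerun_without(ms, [f"rs{i}" for i in range(9)])


def test_joint_clump_pools_and_deduplicates():
    e1 = make_dataset(n=3, seed=1, trait_name="e1", pval=[1e-10, 1e-9, 1e-8])
    e2 = make_dataset(n=3, seed=2, trait_name="e2", pval=[1e-12, 1e-7, 1e-6])
    ld = LDMatrix([f"rs{i+1}" for i in range(3)], np.eye(3))
    kept = joint_clump_for_bma([e1, e2], ld)
    assert sorted(kept) == ["rs1", "rs2", "rs3"]    # union, each SNP once


def test_joint_clump_correlated_cross_exposure_keeps_min_p():
    e1 = make_dataset(n=2, seed=1, trait_name="e1", pval=[1e-6, 0.5],
                      pos=[100, 200])
    e2 = make_dataset(n=2, seed=2, trait_name="e2", pval=[0.5, 1e-9],
                      pos=[100, 200])
    r2 = np.array([[1.0, 0.6], [0.6, 1.0]])
    kept = joint_clump_for_bma([e1, e2], LDMatrix(["rs1", "rs2"], r2))
    assert kept == ["rs2"]        # min-p across exposures wins the clump
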