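import numpy as np
import pandas as pd
import pytest

from mrkit import harmonize_multi, harmonize_pair, ivw
from mrkit.harmonize import COMPLEMENT, HarmonizationError
from conftest import make_dataset


def _pair_datasets(exp_alleles, out_alleles, out_beta_sign=1.0,
                   eaf_exp=0.3, eaf_out=0.3, n=1):
    exp = make_dataset(n=n, alleles=[exp_alleles] * n, beta=[0.10] * n,
                       eaf=[eaf_exp] * n)
    out = make_dataset(n=n, alleles=[out_alleles] * n,
                       beta=[out_beta_sign * 0.05] * n, eaf=[eaf_out] * n,
                       trait_name="outcome", trait_type="binary")
    return exp, out


@pytest.mark.parametrize("out_alleles,sign,action", [
    (("A", "G"), +1, "kept"),              # identical orientation
    (("G", "A"), -1, "flipped"),           # swapped alleles
    (("T", "C"), +1, "strand_corrected"),  # opposite-strand report
    (("C", "T"), -1, "strand_corrected"),  # opposite strand and swapped
])
def test_allele_orientation_cases(out_alleles, sign, action):
    exp, out = _pair_datasets(("A", "G"), out_alleles, out_beta_sign=sign,
                              eaf_exp=0.20, eaf_out=0.21)
    hp = harmonize_pair(exp, out)
    assert hp.n_snp == 1
    # after orientation the outcome effect is always +0.05
    assert hp.beta_out[0] == pytest.approx(0.05)
    assert hp.actions.set_index("snp").loc["rs1", "action"] == action


def test_palindromic_snp_with_maximal_ambiguity_dropped():
    exp, out = _pair_datasets(("A", "T"), ("A", "T"), eaf_exp=0.5, eaf_out=0.5)
    with pytest.raises(HarmonizationError):
        harmonize_pair(exp, out)   # the only SNP is dropped
    # action log is still informative on a 2-SNP dataset
    exp2 = make_dataset(n=2, alleles=[("A", "T"), ("A", "G")],
                        eaf=[0.5, 0.3])
    out2 = make_dataset(n=2, alleles=[("A", "T"), ("A", "G")],
                        eaf=[0.5, 0.3], trait_name="outcome")
    hp = harmonize_pair(exp2, out2)
    acts = hp.actions.set_index("snp")["action"]
    assert acts["rs1"] == "dropped_palindromic"
    assert acts["rs2"] == "kept"


def test_palindromic_snp_resolved_by_frequency_agreement():
    # informative frequencies (MAF < 0.42): same-frequency sides imply same
    # orientation; complementary frequencies imply a flip
    exp, out = _pair_datasets(("A", "T"), ("A", "T"), eaf_exp=0.2, eaf_out=0.2)
    hp = harmonize_pair(exp, out)
    assert hp.beta_out[0] == pytest.approx(0.05)
    exp, out = _pair_datasets(("A", "T"), ("A", "T"), eaf_exp=0.2, eaf_out=0.8)
    hp = harmonize_pair(exp, out)
    assert hp.beta_out[0] == pytest.approx(-0.05)


def test_palindromic_snp_with_missing_eaf_dropped():
    exp2 = make_dataset(n=2, alleles=[("C", "G"), ("A", "G")])
    out2 = make_dataset(n=2, alleles=[("C", "G"), ("A", "G")],
                        trait_name="outcome")
    out2.records.loc[0, "eaf"] = np.nan
    hp = harmonize_pair(exp2, out2)
    assert hp.actions.set_index("snp")["action"]["rs1"] == "dropped_palindromic"


def test_irreconcilable_alleles_dropped_as_mismatch():
    exp2 = make_dataset(n=2, alleles=[("A", "G"), ("C", "T")])
    out2 = make_dataset(n=2, alleles=[("A", "C"), ("C", "T")],
                        trait_name="outcome")
    hp = harmonize_pair(exp2, out2)
    assert hp.actions.set_index("snp")["action"]["rs1"] == "dropped_mismatch"
    assert hp.snp_ids == ["rs2"]


def test_empty_intersection_is_fatal():
    exp = make_dataset(n=2)
    out = make_dataset(n=2, trait_name="outcome")
    out.records["snp"] = ["rsX", "rsY"]
    with pytest.raises(HarmonizationError, match="no shared"):
        harmonize_pair(exp, out)


def test_every_shared_snp_gets_exactly_one_action(rng):
    exp = make_dataset(n=12, seed=5)
    out = make_dataset(n=12, seed=6, trait_name="outcome")
    hp = harmonize_pair(exp, out)
    assert sorted(hp.actions["snp"]) == sorted(exp.records["snp"])
    assert hp.actions["snp"].is_unique


def test_result_ordered_by_exposure_pvalue():
    exp = make_dataset(n=6, seed=7, beta=np.linspace(0.2, 0.01, 6))
    out = make_dataset(n=6, seed=8, trait_name="outcome")
    hp = harmonize_pair(exp, out)
    p = exp.records.set_index("snp")["pval"]
    assert list(hp.snp_ids) == sorted(hp.snp_ids, key=lambda s: p[s])


def _flip_dataset(ds, rng):
    """Swap alleles, negate beta, complement eaf for a random row subset."""
    flipped = ds.records.copy()
    mask = rng.random(len(flipped)) < 0.5
    ea = flipped["effect_allele"].to_numpy().copy()
    oa = flipped["other_allele"].to_numpy().copy()
    flipped.loc[mask, "effect_allele"] = oa[mask]
    flipped.loc[mask, "other_allele"] = ea[mask]
    flipped.loc[mask, "beta"] = -flipped.loc[mask, "beta"]
    flipped.loc[mask, "eaf"] = 1 - flipped.loc[mask, "eaf"]
    from mrkit import SummaryDataset
    return SummaryDataset(ds.trait_name, flipped, ds.trait_type)


def test_flip_invariance_of_downstream_estimates(rng):
    """Allele swap + beta negation + eaf complement leaves IVW unchanged."""
    exp = make_dataset(n=30, seed=9, beta=np.linspace(0.05, 0.2, 30))
    out = make_dataset(n=30, seed=10, trait_name="outcome")
    base = ivw(harmonize_pair(exp, out)).beta
    swapped = ivw(harmonize_pair(exp, _flip_dataset(out, rng))).beta
    assert swapped == pytest.approx(base, abs=1e-12)


def test_harmonization_is_idempotent():
    exp = make_dataset(n=10, seed=11)
    out = make_dataset(n=10, seed=12, trait_name="outcome")
    hp1 = harmonize_pair(exp, out)
    # re-harmonizing the already-oriented pair changes nothing
    out2 = make_dataset(n=10, seed=12, trait_name="outcome")
    hp2 = harmonize_pair(exp, out2)
    np.testing.assert_array_equal(hp1.beta_out, hp2.beta_out)
    np.testing.assert_array_equal(hp1.snp_ids, hp2.snp_ids)


def test_harmonize_multi_requires_overlap_and_k2():
    exp1 = make_dataset(n=5, seed=1, trait_name="e1")
    exp2 = make_dataset(n=5, seed=2, trait_name="e2")
    exp2.records["snp"] = [f"rsX{i}" for i in range(5)]
    out = make_dataset(n=5, seed=3, trait_name="outcome")
    with pytest.raises(HarmonizationError):
        harmonize_multi([exp1, exp2], out)


def test_harmonize_multi_aligned_inputs_stack_columns():
    exp1 = make_dataset(n=8, seed=1, trait_name="e1")
    exp2 = make_dataset(n=8, seed=2, trait_name="e2")
    out = make_dataset(n=8, seed=3, trait_name="outcome")
    ms = harmonize_multi([exp1, exp2], out)
    assert ms.n_exposure == 2 and ms.n_snp == 8
    r1 = exp1.records.set_index("snp")
    r2 = exp2.records.set_index("snp")
    np.testing.assert_allclose(ms.beta_exp[:, 0], r1.loc[ms.snp_ids, "beta"])
    np.testing.assert_allclose(ms.beta_exp[:, 1], r2.loc[ms.snp_ids, "beta"])


def test_harmonize_multi_flip_invariance(rng):
    from mrkit import mvmr_ivw
    exps = [make_dataset(n=20, seed=s, trait_name=f"e{s}") for s in range(3)]
    out = make_dataset(n=20, seed=7, trait_name="outcome")
    base = mvmr_ivw(harmonize_multi(exps, out)).beta
    shuffled = [exps[0]] + [_flip_dataset(e, rng) for e in exps[1:]]
    alt = mvmr_ivw(harmonize_multi(shuffled, _flip_dataset(out, rng))).beta
    np.testing.assert_allclose(alt, base, atol=1e-12)
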