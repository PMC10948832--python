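"""Bayesian model averaging: rank candidate exposures by genetic evidence.

Six aging exposures, one truly causal.  Every exposure subset is scored by
its g-prior marginal likelihood; marginal inclusion probabilities (MIP)
rank the exposures and model-averaged causal effects (MACE) summarize
their effects.
"""

from mrkit import (bma_diagnostics, bma_enumerate, harmonize_multi,
                   joint_clump_for_bma, paper_like_truth,
                   significance_screen, simulate_study)

truth = paper_like_truth(seed=11, n_snp=1200)
exposures, outcome, ld, _ = simulate_study(truth)

# pool every exposure's screened instruments, clump them jointly, then take
# each SNP's effect on every exposure from the full datasets
screened = [significance_screen(ds) for ds in exposures]
pool = joint_clump_for_bma(screened, ld)
ms = harmonize_multi([ds.subset(pool) for ds in exposures], outcome)
result = bma_enumerate(ms, prior_inclusion=0.1)

print(f"{ms.n_snp} joint instruments, "
      f"{len(result.models)} exposure subsets scored")
print("top 5 models by posterior probability:")
for _, row in result.models.head(5).iterrows():
    print(f"  PP={row['pp']:.3f}  {'+'.join(row['subset'])}")
print("marginal inclusion probabilities:")
for name in result.ranking:
    print(f"  {name:18s} MIP={result.mip[name]:.3f}  "
          f"MACE={result.mace[name]:+.3f}")
diag = bma_diagnostics(ms, result, pp_threshold=0.02)
print(f"influence diagnostics flagged {len(diag.flagged_snps)} SNP(s)")
print("-> the causal exposure (telomere_length) should dominate the MIP "
      "ranking; null exposures stay near the prior inclusion rate or below.")
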