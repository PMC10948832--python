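"""Multivariable MR: adjusting correlated exposures against each other.

Simulates two exposures whose instruments are correlated; only exposure 1
is causal.  Single-variable MR finds a spurious signal for exposure 2,
which the joint (multivariable) model removes.
"""

import numpy as np

from mrkit import (SimulationTruth, harmonize_multi, harmonize_pair, ivw,
                   mvmr_ivw, significance_screen, simulate_study)

corr = np.array([[1.0, 0.8], [0.8, 1.0]])
truth = SimulationTruth(theta=[0.5, 0.0], n_snp=300, n_instruments=80,
                        gamma_dist=0.1, exposure_corr=corr,
                        n_exp=200_000, n_out=200_000, case_fraction=0.1,
                        seed=71)
exposures, outcome, _, _ = simulate_study(truth)

for ds in exposures:
    hp = harmonize_pair(significance_screen(ds), outcome)
    est = ivw(hp)
    print(f"SVMR  {ds.trait_name}: beta {est.beta:+.3f}  p={est.pvalue:.2e}")

ms = harmonize_multi([significance_screen(ds) for ds in exposures], outcome)
joint = mvmr_ivw(ms)
for name, b, p in zip(joint.exposure_names, joint.beta, joint.pvalue):
    print(f"MVMR  {name}: beta {b:+.3f}  p={p:.2e}")
print("-> exposure_2's single-variable signal is borrowed from exposure_1 "
      "through correlated instruments; the joint model attenuates it "
      "toward its true value of zero.")
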