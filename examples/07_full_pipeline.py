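"""The complete study design in one call: screen, gate, adjust, rank.

Writes every simulated dataset to disk, runs the pipeline from a
StudyConfig exactly as `mrkit run --config study.yaml` would, and prints
the rendered tables' locations.
"""

import tempfile
from pathlib import Path

from mrkit import (StudyConfig, paper_like_truth, run_full_study,
                   simulate_study, write_ld_matrix, write_sumstats)

workdir = Path(tempfile.mkdtemp(prefix="mrkit_demo_"))
truth = paper_like_truth(seed=3, n_snp=600)
exposures, outcome, ld, _ = simulate_study(truth, randomize_orientation=True)
paths = {}
for ds in exposures:
    paths[ds.trait_name] = str(workdir / f"{ds.trait_name}.tsv")
    write_sumstats(ds, paths[ds.trait_name])
write_sumstats(outcome, workdir / "outcome.tsv")
write_ld_matrix(ld, workdir / "ld.tsv")

cfg = StudyConfig(exposures=paths,
                  outcomes={"outcome": str(workdir / "outcome.tsv")},
                  ld_path=str(workdir / "ld.tsv"),
                  n_sim=500, n_boot=200, seed=3,
                  out_dir=str(workdir / "results"))
tables = run_full_study(cfg)

print(f"tables written under {cfg.out_dir}:")
for name, df in tables.items():
    print(f"  {name}: {len(df)} rows")
sig = tables["svmr"][tables["svmr"]["significant"]]
print("significant SVMR rows (exposure, method, OR, p):")
for _, r in sig.iterrows():
    print(f"  {r['exposure']:18s} {r['method']:16s} "
          f"{r['or']:.4f}  {r['pval']:.2e}")
print("-> significant outcomes pass to the MVMR and BMA stages; the audit "
      "table accounts for every input SNP.")
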