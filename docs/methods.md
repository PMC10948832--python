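# Methods

## Model and assumptions

The package implements summary-data Mendelian randomization. A variant j
is a valid instrument for an exposure when it is (i) associated with the
exposure, (ii) independent of exposure–outcome confounders, and (iii)
affects the outcome only through the exposure. Under those assumptions and
approximately linear effects, the per-SNP Wald ratio Γⱼ/γⱼ identifies the
causal effect; for binary outcomes the effects are on the log-odds scale,
so exponentiated estimates are odds ratios per unit (typically per SD) of
exposure.

All estimators treat the exposure-side effects as measured without error
relative to the outcome side (the NOME approximation): weights are
1/se_out². This is appropriate when instruments are genome-wide
significant in a large GWAS (per-SNP F = (γ̂/se)² well above the
conventional weak-instrument bound of 10); mean and per-SNP F are reported
so the user can check. With weak instruments the IVW slope attenuates by
roughly F̄/(1+F̄), and the Egger intercept absorbs part of the attenuated
slope — a property of the estimators, not of this implementation.

## Estimators and numerical choices

* **IVW.** Origin-constrained weighted least squares, closed-form normal
  equations. Default effects model is multiplicative random effects: the
  fixed SE is scaled by max(1, √(Q/(J−1))), never deflated. A single SNP
  degrades to the Wald ratio with the first-order delta-method SE.
* **MR-Egger.** Instruments are first oriented so every γ̂ⱼ ≥ 0 (both
  betas negated together), the convention that makes the intercept a
  directional-pleiotropy estimand. SEs use the J−2 df analogue of the
  random-effects scaling. Orientation is undefined for sign-ambiguous
  instruments; with genome-wide-significant instruments the sign of γ̂ is
  essentially certain.
* **Weighted median.** Wald ratios ordered; the estimate interpolates the
  weighted empirical CDF (weights γ̂²/se_out², cumulative minus half the
  own weight) at 0.5. The SE is a seeded parametric bootstrap (default
  1000 draws of γ̂ⱼ, Γ̂ⱼ from their sampling normals); no closed form is
  standard.
* **Two-sided p-values** use the normal distribution throughout — the
  summary-data MR convention — and 95% CIs are Wald-type, hence
  log-symmetric on the OR scale. Published MVMR intervals are sometimes
  not log-symmetric (robust or differently rounded constructions); this
  package deliberately reports Wald CIs only.
* **MVMR-IVW/Egger.** Weighted normal equations on the J×K design;
  collinear designs abort with the offending columns named. A
  Sanderson–Windmeijer-style conditional F per exposure (residual
  instrument signal after regressing on the other exposures' effects) is
  attached as a weak-instrument guard, flagged below 10.
* **MVMR-LASSO.** Per-SNP intercepts αⱼ minimize
  Σwⱼ(Γ̂ⱼ−αⱼ−xⱼθ)² + λΣ|αⱼ| by exact blockwise alternation
  (soft-threshold update of α given θ, WLS update of θ given α;
  convergence |Δα| < 1e-8 or 10,000 iterations). The penalty path is 50
  log-spaced values from the data-derived λ_max (smallest λ zeroing all
  intercepts) down to λ_max/1000, warm-started. The chosen valid set is
  the largest zero-intercept set whose post-selection heterogeneity Q
  stays below the χ² 95th percentile at J_valid−K df; the reported
  estimate is post-selection MVMR-IVW on that set.
* **MR-BMA.** Data standardized by se_out; every non-empty exposure
  subset S scored by the variance-marginalized Zellner g-prior marginal
  likelihood (1+g)^(−|S|/2)·[ỹᵀỹ − g/(1+g)·ỹᵀX_S(X_SᵀX_S)⁻¹X_Sᵀỹ]^(−J/2)
  in log space, combined with an independent-inclusion prior (default
  0.1) and normalized. Defaults: g = J (unit information). Because y and
  X share the se_out standardization, g-prior posterior means are already
  on the causal scale. Ties in the model ranking break by smaller subset
  then lexicographic names. Singular subset designs receive PP 0 with a
  warning. Note a consequence of this (standard) marginal likelihood:
  under a true global null the posterior correctly concentrates on sparse
  models, so the average MIP falls *below* the prior inclusion rate —
  equality with the prior would hold only if the causal effects were
  themselves drawn from the prior.
* **Influence diagnostics.** For each model above a PP threshold (default
  0.02), per-SNP Cook's distances from the origin-constrained fit are
  compared against the median of F(|S|, J−|S|), and squared standardized
  residuals (heterogeneity contributions) against χ²₁ at level 0.05/J.
  A numerically exact fit (residual variance below 1e-20 of the data
  scale) yields zero Cook's distances by definition rather than 0/0.
* **Outlier test.** Leave-one-out IVW residuals define the observed
  weighted RSS. The null distribution is a seeded parametric bootstrap
  that redraws both γ̂ⱼ* ~ N(γ̂ⱼ, se_expⱼ²) and
  Γ̂ⱼ* ~ N(θ̂₋ⱼγ̂ⱼ, se_outⱼ²) and *recomputes* the leave-one-out
  estimates per replicate, so per-SNP exceedance p-values carry the
  estimator's own variability; simulating outcome noise alone makes the
  test anti-conservative. Per-SNP p-values are Bonferroni-adjusted over
  J; the add-one Monte-Carlo estimator bounds p ≥ 1/(n_sim+1). The
  distortion test of the original procedure is omitted: the pipeline's
  use is elimination plus re-estimation.
* **Clumping.** Greedy by ascending p, ties broken by (chr, pos, snp) for
  determinism; a candidate is accepted iff every accepted variant is
  either outside the window (different chromosome or > window_kb apart)
  or below the r² threshold. Pairs missing from the LD matrix count as
  independent with a logged warning (strict mode available).
* **Harmonization.** Allele pairs are matched directly, swapped
  (outcome beta negated, frequency complemented), or strand-corrected via
  A↔T/C↔G relabelling. Palindromic SNPs are resolved from frequency
  agreement when the minor-allele frequency is below the 0.42 window on
  both sides, otherwise dropped; missing frequencies always drop them.
  No proxy-variant substitution: absent SNPs are dropped and logged.

## Defaults

| parameter | default | rationale |
|---|---|---|
| instrument p-threshold | 5e-8 | genome-wide significance |
| clump r² / window | 0.001 / 10,000 kb | dominant MR convention |
| palindrome EAF window | 0.42 | standard two-sample MR practice |
| effects model | multiplicative random | conservative when J ≥ 2 |
| outlier n_sim / α | 1000 / 0.05 | Monte-Carlo resolution vs cost |
| median bootstrap | 1000 | SE stability |
| BMA prior inclusion / g | 0.1 / J | sparsity prior, unit information |
| SVMR→MVMR gate | IVW p < 0.05 | nominal screening; a BH-FDR column is emitted but not used for gating |
| meta-analysis | fixed effect | random effects by flag |

All are surfaced in `StudyConfig` and echoed into the run-metadata file.

## Synthetic data: what it emulates, what it does not

The generator mimics the shape of an aging-exposures study: a very large
continuous-exposure GWAS (telomere length, n ≈ 472k) plus five
methylation-clock GWASs (n ≈ 34.5k), and rare binary outcomes
(FinnGen-scale, e.g. 1493 cases / 299,952 controls), via the paper-like
scenario constructor (`paper_like_truth`: instrument counts
121/4/7/22/4/10, effect spreads set so instruments clear 5e-8 at the
stated sample sizes, a lymphoid-leukaemia-scale causal OR of 2.4249 for
the telomere-like exposure and null EAA effects). Summary statistics are
simulated directly — γ̂ = γ + noise with se = 1/√(n·2p(1−p)), binary-scale
se_out = 1/√(n·cf(1−cf)·2p(1−p)) — with effect-allele frequencies uniform
on [0.05, 0.95], optional constant-r² LD blocks laid out consecutively on
chromosomes, directional or balanced pleiotropy with an optional InSIDE
violation, and optional random reporting orientation that harmonization
must undo. When per-exposure instrument counts are given, a block-k
instrument affects other exposures only through the exposure-effect
correlation matrix (shared latent factor); a single count draws all K
effects jointly multivariate normal.

Not modelled: realistic human LD maps, winner's curse, sample overlap,
population stratification, indels/multi-allelics, or allele-frequency
discrepancies between the two samples (both samples share the true
frequencies, so palindromic resolution by frequency is cleaner than in
real data). Passing tests therefore demonstrate correctness of the
estimators and pipeline under the stated sampling model, not robustness
to those real-data complications.

## Test and acceptance problem sizes

Operating characteristics are checked at sizes chosen to keep Monte-Carlo
error decisive at desk scale: type-I error at J = 100 with 2000
replicates; recovery and coverage at J = 50 with 500 replicates;
robustness and MVMR de-confounding at 300 replicates; BMA ranking at
K = 6, J = 60 with 200 replicates. Simulation harnesses use instruments
of genome-wide-significance strength (per-SNP F far above 10), matching
the instrument-selection stage's output; recovery bands are two
Monte-Carlo SEs, coverage bands [0.92, 0.98].

## Known limitations

* No correlated-instrument (LD-aware) IVW; instruments are assumed
  pre-clumped.
* No Steiger directionality filtering, mode-based estimators, or MR-RAPS.
* BMA is exhaustive enumeration only (K ≤ 20); no stochastic search.
* The outlier test's Bonferroni familywise rate sits at its design level
  α, so occasional null flags are expected by construction.
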