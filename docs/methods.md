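# Methods

## The model

Two-sample summary-data MR assumes, for each instrument SNP j, an observed
exposure association β̂_Xj ~ N(γ_j, σ_Xj²) from one GWAS and an outcome
association β̂_Yj ~ N(θ γ_j + α_j, σ_Yj²) from a second, non-overlapping
GWAS. θ is the causal effect of one SD of exposure on the outcome log odds;
α_j is the direct (horizontally pleiotropic) effect of the variant. The
instrumental-variable assumptions are: relevance (γ_j ≠ 0), no
confounding of the variant-outcome relation, exclusion restriction
(α_j = 0), and effect homogeneity. The estimator suite relaxes exclusion in
different directions: MR-Egger allows α_j with nonzero mean provided
cov(α, γ) = 0 (InSIDE); the weighted median allows up to half the weight to
be invalid; the weighted mode requires only that the largest cluster of
per-SNP ratios be valid; MR-PRESSO removes individually detectable
outliers.

## Estimators and numerical choices

**IVW.** β̂ = Σ w_j β̂_Xj β̂_Yj / Σ w_j β̂_Xj², w_j = 1/σ_Yj² — the
closed-form WLS through the origin. Fixed-effects SE = (Σ w β̂_X²)^(-1/2);
the multiplicative random-effects SE inflates by max(1, √(Q/(k−1))). The
automatic rule uses random effects when I² = max(0, (Q−df)/Q) ≥ 50%.
p-values are normal Wald; a single instrument degrades to the Wald ratio
and is labelled as such.

**MR-Egger.** WLS with intercept, same weights, after orienting every SNP
so β̂_X ≥ 0 (without a fixed orientation the intercept is not consistently
identifiable). Inference is t-based on k−2 df, with the residual dispersion
floored at 1 (the usual Egger convention). The intercept and its test are
the pleiotropy test. I²_GX is Cochran's Q of the oriented |β̂_X| around
their inverse-variance-weighted mean with variances σ_X²; below 0.9 the
pipeline substitutes the SIMEX-corrected slope: noise with variance
λσ_Xj² is added for λ ∈ {0, 0.5, 1, 1.5, 2} (B = 200 replicates per λ),
the mean slope is fit as a quadratic in λ and extrapolated to λ = −1, and
the SE comes from a leave-one-replicate-out jackknife.

**Weighted median.** Ratios ordered ascending; standardized cumulative
weights s_j = (Σ_{i≤j} w_i − w_j/2)/Σw with w = 1/se_ratio²; linear
interpolation at s = 0.5. SE by parametric bootstrap (B = 1000 default,
seed mandatory — no hidden global RNG state anywhere in the API).

**Weighted mode.** Argmax of a weighted normal-kernel density over the
ratios evaluated on a 512-point grid, bandwidth φ × 0.9·min(sd, MAD)·k^(−1/5)
(φ = 1 default, exposed because no standard value exists). Degenerate
single-support densities return that point. SE by parametric bootstrap.

**Debiased IVW.** β̂ = Σ w β̂_X β̂_Y / Σ w (β̂_X² − σ_X²). The variance is
the no-overdispersion sandwich form derived from normal moments,
Var = Σ w²[β̂_X²σ_Y² + β̂²σ_X²(β̂_X² + σ_X²)] / (Σ w(β̂_X² − σ_X²))²,
which plugs in the unbiased estimate β̂_X² − σ_X² of γ². A non-positive
denominator (aggregate instrument weakness) is an error, not a number.

**MVMR.** WLS of outcome betas on the L×K exposure-beta matrix, no
intercept, weights 1/σ_Y²; rank deficiency raises an error naming the
collinear exposures. The instrument set is the intersection of each
exposure's harmonizable instruments — the only choice that guarantees a
complete matrix — and sets with L ≤ 3 are refused. Conditional F for
exposure k regresses its betas on the other exposures' betas through the
origin (weights 1/σ_Xk²) and divides the weighted residual Q by
L − (K−1) − 1; cross-exposure sampling covariance is taken as zero
(non-overlapping exposure samples). The no-intercept form is what makes an
orthogonal null co-exposure cost no conditional strength.

**MR-PRESSO.** Observed RSS uses leave-one-out IVW predictions per SNP; the
null distribution comes from nsim (default 1000) parametric redraws of both
β̂_X and β̂_Y about the leave-one-out fitted line, with the +1 permutation
correction, so the smallest attainable global p is 1/(nsim+1). Per-SNP
outlier p-values compare each observed residual to its simulated
distribution and are flagged at Bonferroni 0.05/k; the distortion test
compares the post-removal IVW shift against random removals of the same
number of SNPs (two-sided on |shift|, 0.05). Fewer than 4 SNPs is a
refusal.

**Strength and power.** Per SNP,
R² = 2f(1−f)β² / (2f(1−f)β² + 2f(1−f)Nσ²) and F = R²(N−2)/(1−R²); the
mean-F > 10 convention flags weak-instrument bias. Binary-outcome power
uses the standard non-centrality approximation with case fraction K:
b = K(OR/(1+K(OR−1)) − 1), NCP = N·R²·b²/(K(1−K) − b²), power =
P(χ²₁(NCP) > χ²₁;0.95). This parameterization is approximate by
construction; published power figures computed by other tools can differ
by a few points at the same R².

**FDR.** Benjamini–Hochberg step-up over the family of primary IVW
p-values (one per exposure). Note the adjusted values are monotone and
dominate the raw p-values but are *not* idempotent under re-adjustment —
that is a property of BH itself, not of this implementation.

## Harmonization

Outcome effects are aligned onto each instrument's exposure effect allele:
same alleles kept; swapped alleles negate β_Y and complement the EAF;
complementary-strand pairs are recoded then matched; anything else is
dropped as incompatible. Palindromic SNPs (A/T, C/G) are kept only when
both studies' EAFs lie outside 0.5 ± 0.08 on the same side; the window is a
design choice (frequency-based strand inference is unreliable near 0.5) and
a missing outcome EAF drops the SNP conservatively. Records with missing
EAF fail the MAF filter in strict mode (overridable). LD clumping is greedy
by ascending p with ties broken by snp_id, so output is independent of
input order; variants absent from the user-supplied LD matrix are retained
with a warning rather than silently dropped. Proxy lookup accepts only a
user-supplied table (target, proxy, r² > 0.8); there are no network calls
anywhere in the package.

## Synthetic data

`simulate_study` draws MAFs uniform on (0.05, 0.5), per-SNP effects
γ_j ~ N(0.15, 0.05²) by default, and uses the standardized-trait SE
approximations σ_X = (2f(1−f)N_exp)^(−1/2) and
σ_Y = (2f(1−f)N_out·K(1−K))^(−1/2). Default sample sizes — 22,393 exposure
individuals, 33,674 cases, 449,056 controls — and the default panel of
instrument-set sizes (31/54/6/4/3/1 across six exposures, the first
carrying θ = 0.03) mirror a large published study design of this kind.
Pleiotropy is controlled by (mean, sd) of α_j and an `inside_corr` knob
that correlates α with γ to break InSIDE on demand. Identical seeds give
bit-identical tables.

What the generator does **not** emulate: LD between instruments (the LD
matrix is identity; block structure must be supplied), sample overlap
between the two GWAS, winner's curse beyond what arises naturally from
selecting on simulated p-values, non-normal effect-size distributions, and
exact logistic-model outcome sampling (the case-control SE approximation is
used). Passing simulation tests therefore demonstrate estimator
correctness under the stated generating model, not robustness to every
artefact of real GWAS.

## Test and report scales

The statistical tests run at: 500 replicates for recovery/coverage/type-I
and the pleiotropy and weak-instrument comparisons; 200 replicates at
nsim = 500 for MR-PRESSO detection and calibration; 30 replicates for the
SIMEX improvement check (B = 100, n_exposure = 400 to induce strong
regression dilution); bootstrap B = 200 inside pipeline tests. These sizes
give Monte-Carlo SEs comfortably inside the asserted tolerances while
keeping the default suite fast. The weak-instrument regime uses
γ ~ N(0.03, 0.015²) among 100 candidate SNPs with relaxed p < 5×10⁻⁶
selection, where classical IVW is visibly attenuated and the debiased
estimator recovers most of the gap; the residual bias in both is winner's
curse from selection, which debiasing does not address.

## Known limitations

- The Egger SE floors dispersion at 1; some implementations scale
  differently, so intercept p-values can differ slightly across software.
- SIMEX uses a quadratic extrapolant; with extreme dilution (I²_GX ≪ 0.5)
  the extrapolation itself is the dominant error source and the corrected
  slope should be read qualitatively.
- The distortion test conditions on the observed outlier count; with many
  outliers its random-removal null becomes conservative.
- Conditional F assumes zero cross-exposure sampling covariance; with
  overlapping exposure GWAS panels it overstates strength.
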