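# Methods

## Estimation model

All estimators operate on a harmonized instrument table: per SNP *j*, the
exposure association γ̂*j* with SE σ*Xj* and the outcome association Γ̂*j*
with SE σ*Yj*, both oriented to the same effect allele. The causal effect
β is on the scale of "outcome units per unit of exposure" (log-odds per
log-odds, or per SD for continuous traits); odds ratios are exp(β) with
95% CIs at the fixed normal quantile 1.96 and are rounded to 3 decimals
only at reporting time.

IVW uses first-order weights *w**j* = γ̂*j*²/σ*Yj*², ignoring exposure-side
noise. This is the standard choice and is accurate when instruments are
strong, but it is not exactly unbiased: the estimator carries a
weak-instrument attenuation of roughly 1.5/F̄ in relative terms (F̄ the
mean instrument F-statistic). With the package's default synthetic
instruments (F̄ ≈ 450) that is a ~0.3% shrinkage toward zero — visible in
a 500-replicate mean, irrelevant at single-study precision. The
multiplicative random-effects SE multiplies the fixed-effect SE by
max(1, √(Q/(J−1))): it widens under heterogeneity and never deflates,
which makes the IVW test mildly conservative in calibrated data.

MR-Egger orients rows to γ̂*j* ≥ 0 before fitting, so the intercept is the
average pleiotropic effect in the direction of the exposure-increasing
allele. Its SEs carry the same floored overdispersion and its p-values use
t(J−2), the usual small-sample convention. A design with all exposure
betas equal after orientation is singular and rejected.

The weighted median interpolates the weighted CDF of the ratio estimates
at 0.5 using normalized cumulative weights s*j* = (Σ*k*≤*j* w*k* −
w*j*/2)/Σw. Its SE comes from a parametric bootstrap (default 1000
replicates) resampling both γ̂ and Γ̂ from normals at their SEs; the seed
is an explicit argument and results are bit-reproducible. Inside large
simulation studies the bootstrap can be skipped (`n_boot=0`) when only the
point estimate is needed.

MR-PRESSO follows the published algorithm's structure: the observed
residual sum of squares uses leave-one-out fixed-effect IVW slopes; the
null distribution comes from parametric simulation (default 1000 draws);
per-SNP outliers are declared at Bonferroni α/J; the corrected IVW re-runs
on the outlier-free set; a distortion p-value against random same-size
removals is reported as informational only. The method needs J ≥ 4.
Leave-one-out slopes are computed in O(J) from weighted sums, so the
simulation step is fully vectorized.

## Adjudication and classification

The screen dispatches by instrument count: J = 1 → Wald ratio only;
J = 2 → IVW + Cochran's Q (pleiotropy not assessable); J ≥ 3 adds Egger
and the weighted median; J ≥ 4 adds MR-PRESSO. Under heterogeneity
(Q p < 0.05, J ≥ 3) the weighted median becomes the evaluation method: the
IVW claim survives only if the weighted median is significant (p < 0.05)
with the same sign. Single-instrument pairs are reported but classified
`not_established` — no sensitivity analysis can support them. The
Bonferroni threshold is α/(exposures × outcomes), printed at 3 significant
figures but compared at full precision; p-values in [threshold, 0.05) are
`suggestive`.

p-values are floored at the smallest positive double (5e-324) so the
(0,1] contract survives underflow at extreme z-scores.

## Multivariable MR

The joint design takes the union of SNPs genome-wide significant for at
least one exposure, clumps with each SNP's minimum p across exposures,
applies the MAF/palindrome/F filters to the union (each SNP judged in the
exposure where it is most significant), and intersects all tables with
alleles aligned to one reference orientation. Direct effects come from
the weighted no-intercept multiple regression with overdispersion floored
at 1 and J−K residual df. Per-exposure instrument counts report how many
retained union SNPs are genome-wide significant for that exposure — the
counting convention behind per-exposure "SNP" columns in screening
reports. Conditional F-statistics and MVMR-Egger are out of scope.

## Mediation

β2 and β3 come from univariable two-sample MR runs (not MVMR direct
effects), matching how two-step screens are reported. Two rounding
profiles are exposed because published mediation tables are typically
assembled from already-rounded β columns: `paper_table6` rounds β2·β3 to
3 decimals before dividing by β1 and rounds the percentage to 2 decimals;
`full_precision` is the analytical default. Proportions outside [0, 1]
(inconsistent mediation) are flagged, never clipped. No SE is attached to
the mediated effect by default; a first-order delta-method SE
(β3²se2² + β2²se3²)^½ is available as a labelled extension. Triplets whose
mediator→outcome link is not established (primary p ≥ 0.05 or withdrawn)
are emitted with a `not_established` flag rather than dropped.

## Synthetic data

The generator emulates summary statistics for standardized traits:
se = 1/√(2n·u(1−u)) for effect-allele frequency u ~ Uniform(0.05, 0.95);
binary traits use the same normal approximation with the GWAS's effective
sample size. True SNP-exposure effects are N(0, 0.05) in magnitude,
floored at 8 exposure-side SEs so that the true association clears
genome-wide significance and the observed one does so with ≈99%
probability (the floor exists so that the selection step keeps essentially
all planted instruments; z for p = 5×10⁻⁸ is 5.45). At the default n =
5×10⁵ this yields mean instrument F ≈ 450.

Pleiotropic effects α*j* are applied in the orientation of the
exposure-increasing allele (Γ*j* gains sign(γ*j*)·α*j*): with arbitrary
effect-allele orientation an unaligned "directional" α would cancel in
ratio space and bias nothing. Modes: `balanced` (mean forced to 0),
`directional` (N(μ, σ)), and `inside_violating`, where α gains correlation
ρ with the standardized instrument-strength score of |γ| (a
Gaussian-copula-style construction; the InSIDE assumption names no
mechanism, so this is a documented choice). `pleio_frac` confines
pleiotropy to a subset of SNPs, e.g. 40% invalid instruments. Outliers add
sign-aligned bumps of `outlier_scale` outcome SEs. LD is block-diagonal
with constant within-block r²; blocks sit 20 Mb apart (outside the
clumping window) and SNPs without block structure are spaced 20 Mb apart,
so independence follows from the distance rule rather than silent
assumption. Real LD panels are out of scope.

Mediation triplets carry two instrument sets: exposure instruments
(affecting the mediator through β2 and the outcome through the direct and
indirect paths) and mediator-specific instruments with zero exposure
effect, which make the mediator→outcome step estimable exactly as a real
two-step design uses the mediator's own GWAS hits. Exposure SNPs whose
induced mediator effect β2·γ reaches genome-wide significance can leak
into the mediator→outcome instrument set; their weight share is ~1-3% and
nudges the recovered proportion upward by a few percentage points — a
realistic feature of two-step MR, left in deliberately.

What the generator does *not* emulate: sample overlap between GWAS,
ancestry/stratification structure, real LD panels, allele-frequency
mismatch between studies, and binary-trait liability-scale subtleties.
Passing tests therefore demonstrate correctness of the estimators and
pipeline logic under the stated model, not robustness to those artefacts.

## Validation studies and problem sizes

The packaged studies (mrkit.experiments) use J = 50-100 instruments,
GWAS n = 5×10⁵, and 100-1000 replicates per study — sizes chosen so the
full battery runs in about a minute on one CPU while keeping Monte-Carlo
SEs a few ×10⁻⁴. Observed operating characteristics: IVW and Cochran's Q
type-I error ≈ 0.04-0.06 at α = 0.05 under the null; mean IVW recovery of
a planted 0.2 within ~3 MC SEs (the residual gap is the first-order
attenuation discussed above); Egger-intercept recovery of planted mean
pleiotropy 0.05 well within 3 MC SEs with power ≈ 1 at J = 50; weighted
median ~5× less biased than IVW with 40% invalid instruments; MR-PRESSO
flags planted 10×-scale outliers essentially always, and its corrected
estimate beats the raw one in ~80-95% of replicates (two outliers at 10×
the residual scale displace the raw IVW by only ≈2.8 SEs, which bounds how
often correction can win); end-to-end mediation recovery of a planted
proportion 0.25 within ±0.05.

## Degenerate inputs and tie-breaks

Zero exposure beta → undefined ratio (error, never silently skipped).
Ties in clumping are broken by ascending p with a stable sort. Missing
pairwise LD inside the clumping window is a hard error unless the LD
source declares itself complete. Palindromic SNPs are dropped outright,
never inferred from allele frequency. MAF exclusion is inclusive (≤ 0.01)
and the significance threshold strict (<), following the screening
conventions the pipeline mirrors.
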