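# Methods notes

This note records the modeling choices, defaults, and numerical
details behind `cstdyn`, and what the synthetic benchmarks do and do
not establish.

## Data model and preprocessing

Samples are visits: one swab per (subject, body site, week of life).
Post-menstrual age (PMA) is defined as gestational age at birth (GA)
plus week of life (WOL); pre-term means GA < 37 completed weeks.
Samples flagged as collected during an acute respiratory illness are
excluded from every stage; the illness flag is taken as given (no
symptom scoring is computed).

Per site, OTUs present (count > 0) in fewer than 5% of samples are
removed; the threshold is inclusive ("at least 5%"), and presence is a
count criterion, not an abundance floor. For mixture fitting each
sample is rescaled to a common library of 5000 counts by multiplying
relative abundances and rounding down, so row sums land in
[5000 − n_OTUs + 1, 5000]. For CCA, counts are normalized by
cumulative sum scaling (CSS): the per-sample factor is the sum of
counts at or below the chosen quantile (default 0.5) of that sample's
nonzero counts, rescaled by the median factor. The CSS quantile and
the reference scaling are configurable because the normalization
citation leaves them open. Abundances entering regression models are
arcsine-square-root transformed to stabilize the variance of
proportions.

Cohort summary percentages are rounded half-up to one decimal.
Ethnicity percentages use the known-ethnicity denominator. Sample
counts split hospital versus post-discharge at a configurable
discharge PMA (default 38 weeks) for pre-term subjects.

## Dirichlet-Multinomial mixture CSTs

Estimation is EM. The E-step computes responsibilities from full
Dirichlet-Multinomial log-pmfs (log-sum-exp stabilized, multinomial
coefficient included). The M-step updates mixture weights by posterior
means and each component's α by Minka's fixed-point iteration on the
responsibility-weighted likelihood, which is monotone; the EM
log-likelihood trace is checked non-decreasing at every iteration
(tolerance 1e-8 relative). Defaults: 3 random restarts for final fits
(1 during model scanning), relative tolerance 1e-6, 500 iterations
maximum, α floored at 1e-8. Initialization is k-means on relative
abundances with cluster means scaled to concentration 10 — cheap,
reproducible, and good basins in practice.

Model evidence is a Laplace approximation of the integrated
likelihood over the K·J Dirichlet parameters and K−1 free mixture
weights. The Dirichlet-Multinomial likelihood tends to a positive
constant along rays α → ∞ (the multinomial limit), so a flat prior
makes the integral diverge; we therefore use independent
Exponential(rate 0.1) priors on the α entries and a uniform prior on
the weight simplex, which is diffuse enough to leave the fit untouched
while keeping the evidence finite. The Gaussian approximation is
taken in log-α space (α = e^λ, the Jacobian joining the integrand):
the posterior of a positive concentration parameter is skewed in α
but close to normal in log α, and the substitution roughly halves the
approximation error on quadrature-checkable toys. The expansion sits
at the maximum-likelihood fit; a first-order correction −½ g' H⁻¹ g
(g the log-integrand gradient there) accounts for the small offset
from the exact posterior mode. The Hessian of the negative
log-likelihood is analytic (within-component curvature plus
responsibility cross-terms), mapped to λ by the chain rule. Flat or
negative-curvature directions — redundant
components, boundary fits — are handled by flooring Hessian
eigenvalues at the prior curvature scale (rate², i.e. 0.01) with a
warning; without this floor a degenerate extra component can fake an
arbitrarily good evidence. On two-OTU toys the approximation agrees
with brute-force quadrature of the same integrand to within 5% on the
log scale.

K is selected on ten (configurable) random 80% subsamples scored at
K = 1..K_max. The published phrase "lower bound on the standard error
of the model fit" is ambiguous; we read it as the one-standard-error
rule — the smallest K whose mean score is within one SEM (at the
argmin) of the best mean — which favors parsimony. The alternative
reading (argmin of mean − SEM) is implemented and selectable. Failed
fits leave missing cells; a K with over half its cells missing is
excluded. After the final fit, CSTs are renumbered by decreasing
frequency (ties keep fit order), and posterior ties in assignment go
to the lowest component index.

## Temporal occurrence models

Surface and index smooths operate on the linear probability scale —
the outcome is a posterior membership probability, not a 0/1 logit
outcome — and predictions are clipped to [0, 1] only for reporting,
never during fitting. The engine is penalized least squares: cubic
B-spline bases (dimension 10 per margin, quantile-placed knots) with
second-difference penalties, plus a ridge-penalized block of subject
indicators, which is exactly the mixed-model formulation of a Gaussian
random intercept. Smoothing parameters — one per tensor direction, one
for the subject block — are chosen by GCV on log-spaced grids
(10⁻⁶..10⁶ in 9 steps for smooths; 10⁻⁴..10⁴ in 5 steps for the
subject ridge). Anisotropic penalties matter here: an irrelevant
margin (e.g. GA when occurrence is purely post-natal) can be shrunk
flat without oversmoothing the other margin.

The single-index model parameterizes (a, b) = (cos θ, sin θ) with
θ ∈ (−π/2, π/2), so a ≥ 0 by construction and only the ratio b/a is
identified. The profile criterion (GCV of the 1-D smooth along the
index, subject ridge included) is evaluated on a 181-point θ grid and
refined by golden-section search; the grid guards against multimodal
profiles. A flat profile (criterion range below tolerance) flags the
ratio as indeterminate.

Pattern classification follows the binning rule: convergent when
a, b > 0 and |log2(b/a)| < 1; chronological when the ratio falls below
−1 (or b ≤ 0, the nearest bin in spirit — negative b means prenatal
time does not advance the CST; such fits are flagged) and a logistic
regression of any-occurrence on GA at birth is not significant at
0.05; otherwise idiosyncratic. Thresholds are configurable. No
multiplicity correction is applied to the occurrence test. Complete
separation in the logistic model is reported as p < 1e-6 and counts as
significant; a degenerate outcome (all or no subjects ever occur)
gives p = 1 by convention.

Sequence summaries floor observation PMA to whole weeks; weeks between
consecutive observations take the CST of the nearer observation, an
exact midpoint going to the later one; duplicate (subject, site, week)
keeps the later sample with a warning.

## Cross-site associations

Visits are paired across sites by (subject, WOL). The mixed model for
a taxon at an outcome site uses sum-to-zero (deviation) coding for
each remote site's CSTs, so each coefficient is exactly that CST's
departure from the grand mean and the per-CST Wald tests need no
recombination; the omitted level's test uses the negative-sum
contrast. Covariates: delivery mode, GA at birth, birth season, and a
natural spline of WOL with 14 df (configurable; reduced automatically
when pairs are few). Fits use maximum likelihood so coefficient blocks
are comparable across nested models; the overall remote-CST test is a
Wald-F on the dropped block with residual degrees of freedom, with the
fixed-effect covariance inflated by n/(n − p) to undo the ML variance
bias — under the null this holds the 5% level within Monte-Carlo error
and the p-values are uniform. ΔpseudoR² is the marginal
(fixed-effects) R² difference between the full model and the model
with no remote-CST terms, where marginal R² = fixed-effect variance
over fixed + random-intercept + residual variance. If the reduced
model's likelihood optimization fails, a moment-based OLS fallback
bounds the null R². Benjamini-Hochberg runs per outcome site across
the overall F-test p-values of all tested taxa (all lineage ranks,
counts summed up each lineage prefix before transformation); among
survivors only the most specific significant taxon of each lineage is
reported, equally specific taxa all kept. Both the per-CST Wald filter
and the FDR filter are reported, since either could define edge
inclusion.

Shared-OTU residual correlations regress each shared OTU's
arcsine-sqrt relative abundance on a PMA smooth with a subject random
intercept per site and correlate the paired residuals; OTUs constant
in either site are skipped.

## Cross-validated CCA

Folds block by subject: all of an infant's samples stay together, so
held-out correlations are free of within-subject leakage. Canonical
weights come from classical whitening-SVD on training rows; when the
feature count reaches the training sample count, the whitening is
ridge-regularized (ε = 1e-3 of the mean covariance diagonal) with a
warning, and a 1e-10-scale jitter keeps collinear features harmless.
Held-out "subspace correlations" are Pearson correlations of the
paired projection scores per component; we report mean ± 2×SEM across
folds. Time adjustment replaces features with residuals of a natural
spline regression on PMA at both 14 and 25 df (both reported, since
either could be primary).

## Synthetic cohorts — what they emulate and what they do not

The generator reproduces the study design: 38 pre-term + 44 full-term
by default, pre-term GA uniform on [23, 35.9] weeks, full-term GA
normal(39.6, 1.2) truncated to [37, 42], weekly sampling until a
discharge PMA of 38 weeks then monthly, full-terms monthly from birth,
one year of follow-up. Latent CSTs follow multinomial-logistic
occurrence curves along each CST's own index a·WOL + b·gaBirth —
chosen over a Markov chain because it gives direct ground truth for
single-index recovery. Counts come from per-CST Dirichlet-Multinomial
components; default components dominate disjoint OTU blocks (pairwise
total-variation distance of means > 0.5, i.e. well separated).
Library sizes are log-normal (log-mean 8.5 ≈ 5000 reads median,
log-sd 0.5); depths are not reported in the source cohort, so this is
a field-typical choice. Cross-site dependence enters as rank-copying
of the reference site's CST with probability κ and as a shared
log-normal factor on OTUs common to sites. All draws come from one
counter-based PCG64 stream seeded once, so outputs are byte-identical
across runs.

The generator does *not* emulate: taxonomic realism (lineages are
synthetic placeholders), compositional zero-inflation beyond what the
DM produces, illness episodes (only a flag), sequencing error, or
batch effects. Passing recovery benchmarks therefore shows the
estimators work when their model assumptions hold at realistic sizes
and noise — not that real cohorts satisfy those assumptions.

## Benchmark problem sizes

The shipped checks run at sizes chosen to exercise each property while
keeping a laptop-scale footprint: DMM recovery at n = 300 samples,
60 OTUs, K ∈ {1, 3}, ten replicate datasets, model scan to K_max = 5
on five 80% subsamples; single-index recovery on 30-subject cohorts
(≈ 520 samples) with ten replicates per pattern; association
calibration at 400 pairs with 600 null replicates and 40 power
replicates; chi-squared calibration on 200 replicate cohorts; CCA
checks at 300 samples x 25–30 features, 50 subjects, ten folds.

## Known limitations

* The surface/index smoother selects λ by GCV, not REML; GCV can
  undersmooth small noisy datasets. The subject ridge is a single
  shared intercept variance.
* The Wald-F denominator df is residual-based (n − p); with very few
  subjects a Satterthwaite-type correction would be preferable.
* Laplace evidence at K > 1 ignores label-switching multimodality (the
  K! symmetry adds log K! to the log evidence of every K, shifting
  comparisons only by differences of log K!; at the separations where
  K matters the effect is dominated by the likelihood).
* Classical CCA with ridge whitening is reported; sparse/penalized CCA
  variants are out of scope.
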