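# Methods

## Scoring model

Concentrations of secreted analytes are positive and strongly right-skewed,
so location/scale standardization uses robust statistics: the modified
z-score z = 0.6745·(x − median)/MAD with the raw (unscaled) median absolute
deviation and the normal-consistency constant 0.6745. No outlier exclusion
is applied anywhere. The "dataset" entering each analyte's median and MAD is,
by default, all observations of that analyte pooled across donors, cell
lines and control wells — the pooled convention keeps control means on the
same z-scale as cell-line means; a `per_donor` mode standardizes within
donor instead for sensitivity analysis. When MAD = 0 (more than half the
data at the median) the configurable fallback rescales by the mean absolute
deviation with constant 0.7979 (= √(2/π)), or raises.

LLoQ handling: an analyte is retained only if at most 40% of its
observations fall below its assay lower limit of quantification. Any
threshold in (0.25, 0.43) gives the same retention on the default
synthetic panel; 0.40 is the midpoint-of-feasibility default and is
exposed in the config. Sporadic censored values in retained analytes are
imputed at LLoQ/2 (a standard censored-data convention; `lloq` and `drop`
modes are available).

Quartile groups per analyte take the k = ⌈n/4⌉ highest and lowest
donor-mean scores over the n non-control cell lines (k = 6 at n = 23,
k = 7 at n = 25). Boundary ties break toward the lexicographically smaller
cell-line id so group membership is deterministic.

## Mixed models

All donor-structured analyses use the random-intercept model
y = Xβ + u_donor + ε, u ~ N(0, σ²_d I), ε ~ N(0, σ²_e I). The likelihood is
profiled: at fixed θ = σ²_d/σ²_e, β and σ²_e have closed-form GLS solutions
(per-donor blocks (I + θJ)⁻¹ = I − θ/(1+θn_i)·J, log det = Σ log(1+θn_i)),
leaving a one-dimensional optimization over log θ solved by a coarse
61-point grid plus bounded Brent refinement (xatol 1e-12), with the θ = 0
boundary checked explicitly. A property test confirms the optimum matches a
dense 1000-point grid within 1e-6 log-likelihood units, and the fit matches
(or exceeds, when its optimizer stops early) statsmodels MixedLM.

Conventions:

* **ML vs REML.** ML is the default so likelihood-ratio tests against the
  OLS reduced model are valid; REML is used for variance reporting (for
  balanced one-way designs REML equals the ANOVA method-of-moments
  estimator, which the tests exploit as an oracle). ML's (q−1)/q shrinkage
  of the between-donor mean square costs roughly 0.05 of downward ICC bias
  at 5 donors.
* **LRT.** χ² = 2(ℓ_full − ℓ_OLS) referred to χ²(1) (the plain-df
  convention), with the boundary-corrected ½χ²₀+½χ²₁ mixture p reported
  alongside; the plain p is conservative under the null, which a 300-seed
  calibration test verifies.
* **Denominator df** = n_obs − rank(X) − (n_donors − 1), a containment
  approximation (no Satterthwaite/Kenward–Roger). For 63 observations,
  3 conditions, 3 donors this yields the F(2, 58) shape.
* **Contrasts.** Tukey–Kramer via the studentized-range distribution at the
  containment df. **R².** Nakagawa marginal σ²_f/(σ²_f+σ²_d+σ²_e) and
  conditional (σ²_f+σ²_d)/(σ²_f+σ²_d+σ²_e) with σ²_f the variance of the
  fitted fixed-effect values.
* **Dose–response.** The inverse transformation 1/y is modeled linearly in
  dose with a donor intercept; predicted per-dose means are reported on the
  original scale as 1/fitted.
* **Two-group tests.** Welch by default, Student by flag, exact
  Mann-Whitney for small samples, Kruskal–Wallis for multi-level factors,
  one-sample t for reference-normalized data; an optional Shapiro–Wilk
  pre-test (α = 0.05) routes to the rank test on failure and logs the
  decision.

## Association screens

Spearman ρ is the Pearson correlation of mid-ranks. p-values: exact
enumeration of all n! rank permutations for n ≤ 9 without ties, otherwise
t = ρ√((n−2)/(1−ρ²)) on n−2 df. The gene screen excludes zero-variance
genes, runs on the normalized matrix by default (optionally both counts and
normalized, reported separately), and controls FDR with a Storey-type
q-value (π̂₀ estimated at λ = 0.5) — a deliberate, documented divergence
from null-model-fitting q-value packages; BH is used for the cytokine-pair
and ICC families.

## Quartile differential expression

A self-contained analogue of the count-based NB Wald pipeline; exact
replication of DESeq2 + ashr is explicitly out of scope, so numerical
values on real data would differ while thresholds and call semantics match.

* Filtering removes genes with total count ≤ 3 across samples ("≤ 3 counts"
  is read as the total, the interpretation under which the rule adds
  anything to the detection rule) or detected in < 50% of samples; both
  thresholds configurable.
* Size factors are median-of-ratios over all-positive reference genes, with
  a poscounts-style geometric-mean fallback when no gene is all-positive.
* Dispersions: per-gene method-of-moments α̂ = max(α_min, (s²−μ̄)/μ̄²) on
  normalized counts, moderated by a 50/50 log-space blend toward a robust
  (Huber) trend a + b/μ̄ with b ≥ 0 enforced — a fixed blend rather than
  Cox–Reid empirical Bayes, simpler and adequate for calling at these
  sample sizes.
* Wald stage: per-gene NB log-link GLM with design [intercept, group],
  IRLS vectorized across genes (closed-form 2×2 weighted normal
  equations), ridge 1e-6 on the group coefficient, and a fitted-mean floor
  of 0.5. The floor matters: with one group all-zero the likelihood
  separates completely, weights vanish and the Wald SE diverges
  (Hauck–Donner), so without it such genes — the most extreme biology —
  would never reach significance. Convergence is judged on coefficient
  stability or likelihood stability (the floor flattens the likelihood for
  separated genes while the intercept is unidentified below it).
* Shrinkage: normal prior N(0, τ²) with τ² matched by moments to the
  excess of observed LFC variance over the mean squared SE (floor 1e-4);
  posterior means never exceed the MLE in magnitude and genes with larger
  SE shrink more.
* Calls: BH across tested genes; significant iff p_adj ≤ 0.05 and
  |shrunken log₂FC| ≥ 1 (the shrunken-LFC convention; the MLE column is
  configurable for the threshold).

## Pre-ranked GSEA

Classic weighted-KS running sum with weight exponent p = 1: hit steps
|score|ᵖ/Σ_hits|score|ᵖ, miss steps 1/(N−N_hit); ES is the extremum of
maximal absolute deviation, the leading edge the members at/before (after,
for negative ES) the extremum. The null permutes gene labels (random member
sets of the same size on the fixed ranking) — appropriate because the input
is a pre-ranked list; NES divides ES by the mean |null ES| of matching
sign, p uses the add-one estimator within the same-sign null, BH adjusts
across sets, and a classic GSEA-style FDR q from pooled NES tail ratios is
reported alongside (the two significance conventions in circulation).
Ranking ties break by gene id. A brute-force enumeration oracle (all
C(N,2) placements of pair sets) pins the permutation p in tests.

## Overrepresentation resampling

The statistic is the quartile membership count: for a cell line, the number
of analytes in which it carries the given label; for a tumor type, the
total labeled slots its lines occupy. This is the simplest statistic
consistent with reporting "overrepresentation across analytes" and is
documented as a reconstruction. The null redraws each analyte's quartile
set uniformly and independently (exchangeability across analytes assumed;
correlated-analyte nulls would be an extension), 20,000 permutations for
cell lines and 5,000 per tumor-type grouping, add-one p-values (minimum
1/(n+1), never zero), BH within each family.

## Synthetic data generator

What it emulates: 3 donors × 25 cell lines (+1 unstimulated control at
latent score 0) × 10 analytes, 7 detectable and 3 constructed to fail the
LLoQ rule (their LLoQ sits one total-SD above the log-mean, censoring
~84%); log10-normal concentrations conc = 10^(μ_a + δ_da + λ_a·s_ca + ε)
with donor intercepts δ tuned so the panel's target ICCs span 0.10–0.75 at
a common residual SD of 0.30 log10 units; a standard-normal latent
polarization score per analyte and cell line (analytes can share a latent
factor to induce cytokine–cytokine correlation); a 2000-gene NB count
matrix (dispersion 0.05, library sizes 0.4–0.8M) with 5 planted genes per
analyte whose log2 mean tracks the analyte's latent score with slope 2,
TPM computed with unit gene lengths (counts-proportional — the pipeline
never uses length bias). The log-normal response and log-linear gene link
are modelling choices: concentrations are positive and skewed, and a
monotone link guarantees the rank-based screen sees the planted signal.

Fractionation tables are balanced donor × line × condition draws with a
+1000 pg/mL exosome-only effect by default (donor SD 150, residual SD 200
pg/mL). Dose–response tables place the inverse-scale line through
population means 7.42 pg/mL at dose 0 and 23.02 pg/mL at 5 ng/mL
(slope −0.01827 per ng/mL on the inverse scale) with inverse-scale donor
and residual SDs of 0.0025 — about 2–6% CV of the inverse response,
a tight-replicate regime chosen once so the 4-donor design identifies the
back-transformed means to within 10%; positivity is enforced by resampling.

What it does **not** emulate: assay-specific error structure (plate
effects, dilution series), tumor-type covariance between cell lines,
gene–gene correlation beyond the shared latent factors, length-biased TPM,
or exosome particle counts. Passing recovery tests therefore demonstrates
the pipeline's statistical machinery is correct and calibrated, not that
real experiments of this size would achieve the same power.

All randomness flows from one master seed, split per stage via numpy
`SeedSequence` spawning; rerunning any stage with the same seed is
bit-identical.

## Numerical choices and degenerate inputs

Profile optimization tolerance 1e-12 on log θ (≪ the 1e-6 loglik oracle
band); θ capped at 1e6; MAD = 0 fallback as above; quartiles refuse n < 8;
exact Spearman p falls back to the t approximation under ties with a
warning; constant genes are excluded from screens and floored at
α_min = 1e-8 in dispersion estimation; all-zero samples are a hard error in
size factors; the add-one permutation estimator bounds p away from 0;
single-donor designs raise "random effect unidentifiable" (the
fractionation simulator instead flags its output table when asked for one
donor, so the degenerate design is still constructible for testing).

## Problem sizes in tests

Monte-Carlo test sizes follow the study's shape (3–5 donors, 25 cell
lines, 2000 genes): 100 seeds for ICC recovery, 20 for screen
recovery/null calibration, 8 for the planted-LFC power run, 200 for LRT
and F-test calibration, 20,000 permutations where the resampling defaults
say so. These sizes are the package's own choices balancing Monte-Carlo
error against runtime; the whole suite runs in well under a minute per
heavy module on one CPU.

## Known limitations

Single random-intercept structure only (no crossed/nested effects, no
GLMMs); no Satterthwaite df; the DE stage's dispersion moderation is
deliberately simpler than Cox–Reid; the gene screen's q-values are
Storey-type, not a fitted-null method; the overrepresentation statistic is
a reconstruction; GSEA uses gene-set permutation, not sample permutation.
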