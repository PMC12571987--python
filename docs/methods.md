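# Methods

`gutbrainmr` implements a bidirectional two-sample Mendelian randomization
(MR) screen with two-step cytokine mediation, of the kind used to ask
whether gut-microbiota abundances causally influence brain structural
connectivity. This note records the statistical model, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## The causal model and estimators

For SNP j, let `beta_exp_j` (SE `se_exp_j`) be its per-allele association
with the exposure and `beta_out_j` (SE `se_out_j`) with the outcome, from
non-overlapping GWAS samples. Under the instrumental-variable assumptions
(relevance, independence, exclusion restriction) each SNP provides a Wald
ratio estimate `beta_out_j / beta_exp_j` of the causal effect.

* **IVW** pools the ratios with first-order weights
  `w_j = beta_exp_j^2 / se_out_j^2` (equivalently weighted regression of
  the outcome betas on the exposure betas through the origin). The
  default is multiplicative random effects: the fixed-effect SE
  `1/sqrt(sum w_j)` is inflated by `max(1, sqrt(Q/(k-1)))`, where Q is
  Cochran's heterogeneity statistic. This mirrors the default of the
  dominant two-sample MR toolkit; a fixed-effect variant is a flag.
  First-order weights ignore exposure-side sampling error, which induces
  the usual small regression-dilution bias (about -0.006 at the default
  study scale; see the calibration numbers the acceptance script
  recomputes).
* **MR-Egger** adds a free intercept; a nonzero intercept estimates the
  average directional pleiotropy. The intercept is orientation-dependent,
  so pairs are reoriented to `beta_exp >= 0` before fitting. Inference
  uses t-tests on k-2 df with the residual variance factor bounded below
  by 1.
* **Weighted median**: the ratio at cumulative normalized weight 0.5,
  linearly interpolated; consistent while valid instruments carry more
  than half the weight. SE by parametric bootstrap of the ratios
  (weights held fixed), seeded.
* **Simple/weighted mode**: argmax of a normal-kernel density of the
  ratios, bandwidth `phi` times the modified Silverman rule
  `0.9 min(sd, scaled MAD) k^(-1/5)`, with `phi = 1`; the weighted
  variant weights each ratio by its inverse variance. SE by the same
  bootstrap.

Every estimate is reported with `exp(beta)` and
`exp(beta ± 1.96 se)`; the "OR" label is kept for continuous
connectivity traits to match the reporting convention of the screens
this package emulates.

## Sensitivity battery

* **Cochran's Q** with first-order IVW weights, chi-square on k-1 df.
* **Egger intercept test** as above.
* **MR-PRESSO**: the observed residual sum of squares uses leave-one-out
  IVW slopes; the null is built from `n_sim = 1000` parametric draws of
  both beta vectors (the original tool's default simulation count — the
  studies this emulates do not state theirs). The per-SNP outlier test
  Bonferroni-corrects the empirical residual p-values over k, following
  the original method. The distortion test compares the outlier-removed
  slope with the distribution of slopes after removing random subsets of
  the same size. Monte-Carlo p-values are `(1 + #exceedances)/(1 + n_sim)`
  and therefore never zero. Outlier-corrected estimates are reported
  alongside raw ones, never silently substituted.
* **Leave-one-out** IVW and plot-ready scatter/funnel tables (no figure
  rendering; the tables carry everything a plot needs).

## Instrument selection and harmonization

Defaults follow standard microbiome-MR practice: exposure taxa use
p < 1e-5 with greedy LD clumping at r² = 0.1 within 500 kb; brain
connectivity and cytokine traits use p < 5e-6, r² = 0.01, 10,000 kb.
Thresholding is strict (<). Clumping requires an explicit LD matrix (or a
declared-independence mode) — no remote reference panels. Instrument
strength uses `R² = 2 f (1-f) beta²` (exact for a standardized trait,
and the generative model of the simulator); the approximation
`z²/(z² + N)` is available because published screens rarely state which
they used. `F = R² (N-2)/(1 - R²)`; SNPs with F strictly below 10 are
excluded (F = 10 is kept).

Harmonization aligns outcome records to the exposure effect allele via
direct, swapped, strand-complemented, or complemented-and-swapped
matching. Palindromic (A/T, C/G) variants are dropped unconditionally by
default — stricter and deterministic compared with the frequency-rescue
rule some toolkits apply; a rescue mode (keep when both EAFs are at
least 0.08 from 0.5, orient by frequency agreement) exists for
comparison. A palindrome on the exposure side is reported as
`palindromic` even when the SNP is also absent from the outcome file.

## Two-step mediation

With `beta1` (exposure→mediator), `beta2` (mediator→outcome) and
`beta_total` (exposure→outcome), all from IVW, the mediation effect is
the product `beta1 * beta2`, its first-order delta-method SE is
`sqrt(beta1² se2² + beta2² se1²)` (the exact product variance, adding
`se1² se2²`, is a flag), and the mediated proportion is
`100 * beta1 * beta2 / beta_total`. The proportion CI scales the
mediation-effect CI by `1/beta_total`, treating the total effect as
fixed — published delta-method statements in this literature do not
propagate total-effect uncertainty, and in simulation the resulting
interval still covers the true proportion in >= 90% of replicates.
Proportions outside [0, 100]% (inconsistent mediation) are reported
with a warning, not clipped. Screening gates: step 1 at 0.05/211,
step 2 at 0.05/41, and the total effect must pass the forward family
(0.05/211); each failed triple is logged with its failing gate.

## Synthetic-data generator

Summary statistics are simulated directly at the summary level — the
standard two-sample MR benchmarking design — rather than through
individual-level genotypes: for SNP j with MAF `f_j` drawn uniformly
from (0.05, 0.5), the instrument effect is `gamma_j ~ N(0, gamma_sd²)`
(zero for non-instruments), the mediator effect `beta1 * gamma_j`, the
outcome effect `beta_direct * gamma_j + beta2 * delta_j + alpha_j`, and
estimates add `N(0, se²)` noise with `se = 1/sqrt(2 f (1-f) n)` for a
standardized trait. Default sample sizes mirror the consortium studies
this pipeline targets (exposure 18,340; outcome 26,333; mediator 8,293),
with about a dozen instruments per taxon (`gamma_sd = 0.06` puts typical
instruments just above the relaxed p < 1e-5 threshold at those sample
sizes, matching how microbiome instruments behave) and a total effect of
0.15, the scale of the significant associations such screens report.

Directional pleiotropy `alpha_j ~ N(pleio_mean, pleio_sd²)` is oriented
with the exposure-increasing allele (`sign(gamma_j)`): allele coding is
arbitrary, so an unoriented constant shift would cancel under the Egger
`beta_exp >= 0` reorientation and no estimator could see it. Balanced
(mean-zero) pleiotropy is unaffected by the orientation.

All randomness flows from one scenario seed through
`numpy.random.SeedSequence` spawning, so allele assignment, true
effects, per-trait noise and dialect corruption are independently
reproducible streams; equal seeds give byte-identical output files.

What the generator does **not** emulate: realistic human LD (blocks are
exchangeable with constant within-block r²), winner's curse from
selecting instruments on the exposure scan (benchmark fixtures pick
instruments by true status; a selection-by-p path exists through the
ordinary pipeline), case-control traits, sample overlap between the two
GWAS, and mediator-specific instruments — the mediator inherits the
exposure's variants, so a noise-free mediation fixture estimates
`beta2 + beta_direct/beta1` in step 2 rather than `beta2` (real screens
use the mediator's own GWAS hits). Passing calibration tests therefore
demonstrates correctness of the estimators under the stated generative
model, not robustness to everything real GWAS data can do.

## Benchmark study sizes and fixture choices

The replicate studies (run both by the test suite and by
`scripts/acceptance.py`) use: 500 replicates for bias/coverage (k = 50
instruments, no pleiotropy), 500 null replicates for type-I error
(k = 50 — random-effects IVW is conservative at small k, and k = 50 is
where its large-sample calibration holds), 100 replicates for the
planted-outlier study (k = 30, one 10-SE offset), and 500 replicates for
the half-invalid-instrument comparison (k = 20, offset 0.1 oriented with
the exposure-increasing allele on 10 instruments). The planted outlier
lands on the highest-weight instrument (largest `|beta_exp|/se_out`): an
offset on a near-zero-weight instrument barely moves IVW, so whether its
removal helps is a coin flip; the fixture must distort the pooled
estimate for outlier *correction* (as opposed to detection, which works
regardless) to be measurable.

## Numerical choices and degenerate inputs

* Serialization uses `%.16e` (17 significant digits) and the reader
  parses floats through Python's correctly-rounded `float()`, so
  write/read round-trips are bit-exact.
* p-values are floored at the smallest positive normal double; Wald
  ratios with `beta_exp = 0` raise; IVW of an empty set raises; Egger,
  median and mode require k >= 3, MR-PRESSO k >= 4, Q and leave-one-out
  k >= 2. Pipeline orchestration converts these into logged skips, not
  failures (real screens run taxa with as few as 4 SNPs).
* Clumping ties on p are broken lexicographically by snp_id, making the
  greedy order — and hence the output — deterministic; the output is
  asserted pairwise-valid on every run.
* The mode estimator falls back to the common ratio value when the
  bandwidth degenerates (all ratios equal).
* All identical ratios give Q exactly 0 and p exactly 1.

## Known limitations

* Second-order IVW weights and exact Egger SIMEX-style corrections are
  out of scope; first-order weights are the stated convention.
* No Steiger filtering, multivariable MR, MR-RAPS, or radial MR.
* The reverse screen reuses the forward machinery with the
  connectivity-trait selection parameters; it does not model shared
  instruments between directions beyond what the data imply.
* Enrichment analysis of mediator gene sets is out of scope (external
  web services, database-version dependent).
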