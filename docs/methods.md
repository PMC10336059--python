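# Methods

## The statistical model

Each behavioral trait is modelled as a Gaussian repeated-measures response

    y_ij = x_ij' b + u_i + e_ij,    u_i ~ N(0, V_ind),   e_ij ~ N(0, V_e)

for individual i in trial j, with fixed effects x_ij = (intercept, trial
number, body length, sample origin). Trial and length are mean-centered;
sample enters as a reared-vs-wild indicator. The adjusted repeatability —
"adjusted" because the fixed effects are controlled before the variance is
split — is R = V_ind / (V_ind + V_e), computed on every posterior draw so
that its 95% credibility interval (2.5% and 97.5% quantiles) is exact
under the posterior. Because the ratio is nonlinear, the posterior mean of
the per-draw ratio and the ratio of posterior-mean variances differ
slightly; reports show the per-draw summary and note the plug-in value.

For trait pairs the same model is fitted bivariately with a 2×2
between-individual covariance G and residual covariance R. Per draw,
r_ind = G12/√(G11·G22), r_e = R12/√(R11·R22), and the phenotypic
correlation r_p = (G12+R12)/√((G11+R11)(G22+R22)). A behavioral syndrome
is declared when removing both covariances (off-diagonals of G and R fixed
at 0) raises the DIC by more than 2.

## Gibbs sampler

All full conditionals are conjugate, so the sampler is a plain Gibbs sweep
with no tuning parameters:

* fixed effects — Gaussian, precision X'X/V_e + I/10^10;
* random intercepts — independent Gaussians (2×2 in the bivariate case,
  with one shared posterior covariance per group size);
* variances — scaled inverse-chi-square (univariate) or inverse-Wishart
  via Bartlett decomposition (bivariate).

Priors follow the conventional flat/uninformative structure for this model
class: N(0, 10^10) on each fixed effect and inverse-Wishart with scale =
identity and df = dim − 1 + 0.002 on each (co)variance (0.002 for scalar
variances, 1.002 for 2×2 blocks). The constrained bivariate model samples
its two diagonal variances with the same per-variance df (1.002) so that
DIC comparisons between the constrained and unconstrained fits share prior
marginals. Prior parameters are constructor arguments; halving/doubling
the variance-prior scale moves posterior variance means by well under the
Monte-Carlo error at the sample sizes used here (q ≥ 30 individuals).

Chain defaults mirror standard practice for this model family: 13,000
iterations, 3,000 burn-in, thinning 10 for univariate fits; 100,000 /
10,000 / 100 for bivariate fits. Validation and the acceptance script run
the bivariate chains at 20,000 / 2,000 / 20 — a deliberate scale-down that
keeps 900 retained draws; posterior means at the two lengths agree within
Monte-Carlo error (see the chain-invariance test). A single chain is run,
as is usual with fully conjugate Gibbs; convergence is checked with a
Geweke z-score (warning-only at |z| ≥ 2) rather than multi-chain R-hat.
Samplers are bit-reproducible given `random_state`.

**DIC.** Deviance is −2× the Gaussian log-likelihood *conditional on the
random effects*; DIC = D̄ + pD with pD = D̄ − D(θ̄) evaluated at the
posterior means of the fixed effects, random effects, and residual
(co)variance (the classical Spiegelhalter form, at the individual-level
focus). The repeatability test refits with the random term removed; ΔDIC
= DIC_constrained − DIC_full, significant above 2.

**pMCMC** for a fixed effect is 2·min(P(draw>0), P(draw<0)), floored at
1/n_draws.

**Backward reduction** removes, per step, the fixed term whose removal
lowers DIC most, stopping when no removal lowers it; intercept and random
term are never candidates. DIC ties within 0.01 drop the later-listed term
(trial < length < sample), making selection deterministic.

**Between-sample variance test.** Wild and reared samples are compared
with a two-sided F-test on per-individual mean trait values (larger
variance over smaller; p doubles the upper tail). Per-individual means
rather than raw observations are used so that within-individual
replication does not inflate the df; raw values can be passed instead.

## Trajectory metrics

* Detection ⇔ outside refuge, so time outside = detected seconds.
* Minimum distance imputes the refuge-to-stimulus distance (250 px novel
  object, 350 px conspecific) only when a test has *zero* detections; the
  per-second imputation alternative would change the minimum only in that
  same case, but the per-test reading matches how an individual that never
  emerged is scored. Interaction time uses a closed comparison
  (distance ≤ 100 px).
* Distance and turning angles treat detections separated by undetected
  seconds as consecutive (no interpolation across refuge visits);
  zero-length displacements are skipped in angle computation.
* Von Mises fit: μ is the circular mean; κ solves I1(κ)/I0(κ) = r̄ with
  the Best–Fisher closed-form start refined by Newton iterations on
  exponentially-scaled Bessel functions. κ is capped at 500 (flagged
  `saturated`) because the MLE diverges as r̄ → 1.
* Utilization areas use a binned kernel density estimate: detections are
  histogrammed on a 256×256 grid over the arena and smoothed with a
  Gaussian kernel, per-axis Silverman bandwidth (σ̂·n^(−1/6) in 2-D), in
  reflect mode — the standard reflection correction for a bounded arena.
  The 95%/50% area is the highest-density region: cells accumulated in
  decreasing density order until the probability mass is covered, times
  the cell area. Grid, bandwidth, and bounds are arguments. On 10^5
  uniform points over a known square the 95% area lands within 1% of the
  analytic value; a point mass reproduces the single-kernel closed form
  2πh²·ln(1/(1−p)).
* Activity metrics require ≥ 20 detections; below that they are omitted
  and flagged.

## PCA scoring

PCA runs on the correlation matrix (standardized metrics): the metric
battery mixes seconds, pixels, and squared pixels, so covariance PCA would
be dominated by units. One decomposition per axis pools both samples and
all trials, giving each individual-trial a score on a common axis.
Because a principal component's sign is arbitrary, each axis declares an
orientation metric whose loading is forced non-negative, and metrics where
smaller = more of the trait (minimum distances, latencies) are negated
first, so positive score always means more exploratory / social / bold /
active. Exploration and sociability scores pass through a shift-log,
log(y − min(y) + 1), before model fitting; PC scores are signed, so some
positivity shift is unavoidable and the shift constant is recorded in the
output metadata.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture.

*Trait tables* follow exactly the mixed model above; a paired variant
draws individual effects and residuals from bivariate normals with
specified r_ind and r_e, so the implied phenotypic correlation is
(r_ind·√(Vi1·Vi2) + r_e·√(Ve1·Ve2)) / √((Vi1+Ve1)(Vi2+Ve2)). Body lengths
default to 12.15 ± 1.01 cm, the observed juvenile distribution; samples
split half wild, half reared.

*Trajectories* are a correlated random walk sampled at 1 Hz: Von Mises
turning angles, exponential step lengths (tracking data constrain only the
angles; a one-parameter positive step law is the minimal choice),
reflective aquarium walls, and a two-state per-second Markov chain for
refuge occupancy — detections exist iff outside, matching the operational
equivalence of "not detected" and "in the refuge". On exit the fish
reappears just outside the refuge with a fresh heading; steps that would
enter the refuge are re-aimed, so no detection ever falls inside it. An
optional taxis term blends the heading toward a stimulus point, used by
the pipeline to make interaction metrics responsive to the latent trait.

The pipeline's demo couples the two generators: each axis's latent trait
modulates the refuge-exit odds (logit shift of 2 per latent unit), the
activity step length (factor e^0.4 per unit), stimulus attraction, and the
Poisson/log-normal annotation metrics (approach counts, feeding
latencies). Gains were fixed once so that score-level repeatabilities land
in the 0.15–0.55 range reported for real fish batteries. What the
generator does *not* emulate: detector misses while outside the refuge,
localisation error, within-refuge dwell-time structure beyond the
geometric (Markov) dwell, smooth swimming dynamics, or direct
behavior–covariate feedback. Consequently, passing recovery tests
demonstrates the *inference machinery* is correct and calibrated — not
that real tracking noise is benign; indeed the demo shows the realistic
attenuation of score-level R and r_ind relative to latent truth.

## Validation scale and numerical choices

Recovery studies run at 70 individuals × 4 trials (the scale of a typical
arena experiment, and of the motivating one): 50 seeded cohorts for
repeatability bias/coverage, 20 for syndrome recovery and 20 nulls for the
ΔDIC false-positive rate — sizes chosen as the smallest at which the
Monte-Carlo error of the summaries is comfortably below the tolerances
checked. Degenerate inputs are defined rather than left to chance:
zero-detection tracks impute, < 3 detections refuse turning angles, all-
identical angles saturate κ, constant metric columns and singular designs
raise errors naming the offending column, zero response variance raises,
and an all-equal denominator group yields a flagged infinite F.

## Known limitations

Gaussian responses only; random intercepts only (no random slopes); no
parameter-expanded priors, so very small variance components mix slowly;
single-chain diagnostics; DIC is reported at the conditional focus only.
The shift-log transform is an implementation choice for making signed PC
scores log-transformable, not a canonical procedure. The refuge dwell
model is an assumption about the simulator, not an inference about fish.
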