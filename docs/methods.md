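# Methods

This note documents the models, algorithms, defaults and known
limitations of `listeneff`. It is written for users who want to know what
the package computes and why, not just how to call it.

## The decision model

Each trial of the speech-in-noise task is a speeded yes/no decision,
modelled as a race between two linear ballistic accumulators — one per
response option, labelled by whether it produces the *correct* or the
*incorrect* answer. Accumulator `j` starts at a point drawn uniformly on
`[0, A]`, accumulates evidence at a constant trial-specific rate drawn
from `Normal(v_j, sv)`, and finishes when it reaches the threshold
`b = A + k` (parameterising the threshold by the gap `k > 0` makes
`b > A` structural rather than a constraint to enforce). The first
accumulator to finish determines the response; the decision time plus the
non-decision time `t0` (perceptual encoding and motor execution) gives
the observed RT. `sv` is fixed to 1 as the scaling constraint. An
accumulator whose sampled rate is negative never finishes; a trial in
which neither finishes has no response. The derived quantity
`response caution = k + A/2` is the average evidence needed to respond.

Closed forms for the single-accumulator first-passage density and CDF use
the standard normal `Φ`/`φ`; the joint density of (choice, RT) is the
winner's density times the loser's survival function (the "defective"
density, with no renormalisation for the no-finisher event). Densities
are floored at 1e-300 before logging so that numerical underflow is
distinguishable from the structural zero at `t ≤ t0`, which yields an
explicit `-inf`.

**Missing responses.** Responses slower than the 3 s deadline are
recorded as missing. They enter the likelihood as latent RTs above the
deadline (one parameter per missing trial, sampled on a log-offset scale
above the deadline, capped at 10 s by default), with accuracy assumed at
chance: each missing trial contributes
`log(0.5·g_correct(t_latent) + 0.5·g_incorrect(t_latent))`.

## Listening efficiency

The primary metric is the differential drift rate
`vDiff = v_correct − v_incorrect`, the net rate of evidence accumulation
toward the correct response. It is computed per posterior draw from the
group-level means (natural scale), separately per condition and trial
type; condition-level contrasts are the arithmetic mean over the three
ordered conditions and the OLS slope on equally spaced condition codes
(for three points, exactly `(Hard − Easy)/2`). Between-group differences
are per-draw subtractions (NH − CI). Intervals are 95% highest-density
intervals: the shortest window containing `⌈0.95·n⌉` sorted draws, ties
broken toward the smaller lower bound. Cliff's delta on posterior-
predicted data uses, per draw, one predicted participant-level value per
participant (a pooled-draw variant is available).

## The hierarchical model

Each participant has 15 free parameters: 12 drift means (2 accumulators ×
3 conditions × 2 trial types) plus `A`, `k`, `t0`. All 15 enter the
individual-level model on the **log scale**: the individual log-parameter
vectors are multivariate normal within group, `log θ_i ~ MVN(μ_g, Σ_g)`,
with group-specific mean and full covariance. The log transform keeps
every parameter positive and, importantly, keeps the incorrect-response
drift identified: at near-ceiling accuracy the likelihood barely
constrains `v_incorrect` from below, and on the natural scale it can
wander to large negative values, dragging the threshold and non-decision
time with it. The structural parameters are hierarchical within group by
default; a config switch (`structural_hierarchical=False`) collapses them
to a single shared value per group (this variant is biased for `t0` —
a shared `t0` must sit below the fastest trial of the fastest
participant — and is provided for comparison, not as the default).

**Priors** (all configurable):

| parameter | prior | rationale |
|---|---|---|
| group mean log drift, correct | Normal(1.0, 1.0) | median 2.7 evidence units/s; rates 0.2–8 within ~2 SD |
| group mean log drift, incorrect | Normal(−0.5, 1.0) | error-evidence accumulation is slow in tasks performed well above chance |
| group mean log A, log k, log t0 | Normal(0, 1) | sub-second geometry of speeded two-choice tasks |
| group covariance Σ_g | Inverse-Wishart(df = 18, scale = 2·diag(0.04)) | prior mean variance 0.04 (log-SD 0.2), weakly informative; conjugate |
| latent missing RTs | flat on (deadline, cap] via log-offset | the data term is the chance-accuracy density |

These defaults were validated by simulate-and-recover at the study's
scale; the accumulator-specific drift prior locations in particular
remove a recovery bias in which a prior-inflated incorrect drift
suppresses the predicted RT tail and the fit compensates with a lower
`t0` and higher threshold.

## Sampling

No gradient-based probabilistic-programming backend is required: the
sampler is a blocked adaptive Metropolis-within-Gibbs scheme in which
conditionally independent blocks are updated in parallel and conjugate
blocks are drawn exactly.

* **Conjugate group level.** Given the individual vectors, the group mean
  is a multivariate-normal draw and the group covariance an
  inverse-Wishart draw (inverse-gamma per coordinate in diagonal mode).
* **Per-participant random-walk blocks**, vectorised across participants:
  2-dim drift-cell blocks (correct/incorrect pair per condition × trial
  type, only that cell's trials re-evaluated), a 3-dim structural block,
  and a full 15-dim joint block. Proposal scales follow Robbins-Monro
  adaptation toward target acceptance rates during warmup (moments reset
  mid-warmup to drop the initial transient), with per-block full
  covariance estimated by Welford updates for small correlated blocks;
  proposals are frozen after warmup so the sampling phase is Markovian.
* **Ridge moves.** The LBA posterior has well-known soft ridges: decision
  times `(b−a)/v` are invariant under a common rescaling of `A`, `k` and
  all drifts (constrained only through the fixed `sv = 1`), and `t0`
  trades off against the decision-time distribution. Dedicated moves
  traverse them: a scale move translating `log A`, `log k` and all log
  drifts by a common amount; a t0-shift move adding `δ` seconds to `t0`
  with a compensating rescale of `A`, `k` and drifts that preserves each
  participant's mean RT (a deterministic proposal with exact triangular
  Jacobian `Σ log(t0/(t0+δ))`); both in per-participant and group-level
  (mean + all members translated together, leaving the pooling prior
  untouched) versions.
* **Weakly identified coordinates.** The incorrect-drift coordinates are
  refreshed by an independence proposal from their conditional prior
  given the rest of the vector (the Metropolis ratio reduces to the
  likelihood ratio), and a group-level shift translating the six
  incorrect-drift group means together with every member jumps at the
  marginal scale instead of the sigma/sqrt(n) crawl of a centered Gibbs
  cycle.  A deviation-rescale (expansion) move on the structural
  coordinates — multiply every member's deviation from the group mean by
  a common factor, with Jacobian n·eps — completes the affine family and
  addresses the centered hierarchy's funnel.
* **Latent missing RTs** move by random walk on `log(t − deadline)`.

`thin` internal sweeps are run per retained draw (default 5; the recovery
experiments use 14), so the retained-draw contract (chains × iterations)
matches the published sampling plan while the effective sample size is
set by the sweep count. The per-trial likelihood used inside the sampler
is a fused numba kernel (gather + density + per-participant reduction,
specialised to `sv = 1`); its equality with the reference numpy
implementation is covered by tests, and the numpy path is used when numba
is unavailable.

Convergence is monitored by rank-normalised split R-hat (via arviz) for
every group-level parameter; any value outside [0.99, 1.01] triggers a
warning naming the offending parameters. A non-centered parameterization
(`θ_i = μ + σ·ξ_i`, diagonal covariance) is implemented alongside the
centered one with coordinate-wise updates plus interweaving moves
(translate μ or rescale σ with ξ compensating so θ — and hence the
likelihood — is unchanged), and the two are cross-checked for agreement
on a small instance; the centered form is the default because the
conjugate group-level updates it enables dominate for data this
informative.

## Synthetic data generator

The generator defines the study conditions end-to-end:

* **Design**: 24 CI + 25 NH participants (two completing one run only),
  2 runs × 3 SNR blocks (Easy +20 dB, Med +10 dB, Hard +4 dB; labels
  only — no audio is synthesised) × 28 trials (18 sentence + 10 null,
  randomly interleaved), 3 s response deadline. Block order and the
  6–10 s stimulus-onset jitter are carried as schedule metadata and enter
  no likelihood.
* **Participants**: individual log-parameter vectors drawn from the group
  multivariate normal and exponentiated; the default group means place
  the sentence/null differential drifts, response caution and `t0` at the
  published group-level posterior means, with a baseline incorrect drift
  of 0.5 (the published analysis reports only the differentials; 0.5 is
  typical of two-choice fits of high-accuracy tasks, and `A = 1` with
  `k = caution − A/2` completes the geometry). Between-participant log-SD
  defaults: 0.15 for drifts, 0.10 for structural parameters — modest
  individual differences around the group means. Negative generative
  drifts remain expressible through a per-accumulator sign field
  (default all +1).
* **Behaviour**: every trial runs the race sampler; trials with RT beyond
  the deadline or no finisher are missing. Sentence trials have a 50%
  probe-present design, so the recorded yes/no response is derived from
  the (simulated) correctness and a random ground-truth answer.
* **Ratings**: one [0, 1] visual-analog rating per participant ×
  condition × question (effort, intelligibility, disengagement) from the
  ordered-beta generative model, with group × condition cell effects at
  the logits of the published cell means and participant random
  intercepts (SD 0.5).
* **Scores**: per-instrument tables built by the linear-Gaussian
  construction `z = ρ·std(e) + √(1−ρ²)·ε` against the individual true
  efficiencies, mapped into the instrument's range (midrange centre, one
  sixth of the range per SD) and clipped. Clipping slightly attenuates
  the realised correlation, so exactness tests use `clip=False`. The
  default target correlations mirror the published CI-group associations
  (SSQ12 +0.4, EAS −0.3, TRT −0.4) with zero for the NH group. The
  generative link between scores and efficiency is a modelling stand-in:
  the analysis only ever *measures* correlations, and nothing downstream
  depends on this construction.

What the generator does **not** emulate: real speech acoustics and their
reverberation, serial-position or fatigue effects within blocks,
non-stationary strategies (parameters are fixed across trials within a
cell), response bias (no per-response start-point asymmetry in the
generative defaults), and any physiological channel. Passing tests
therefore demonstrate statistical correctness of the pipeline under the
stated generative assumptions, not robustness to real-data violations of
them.

## Association analysis

Individual sentence-trial differential drifts, averaged across
conditions, are extracted per posterior draw ("plausible values"), giving
one sample correlation `r_s` with an external score per draw (Pearson, as
in the plausible-values literature). The population-correlation posterior
mixes, over draws, the exact posterior `p(ρ | r_s, n)` under a uniform
prior on ρ — the bivariate-normal sampling density of the sample
correlation, evaluated with `scipy.special.hyp2f1` on a fixed grid of
2,001 points over (−1, 1) and normalised by the trapezoid rule (the
Fisher-z approximation is kept as a test oracle). When more than 2,000
draws are supplied, an evenly spaced deterministic subsample bounds the
grid-mixture cost; the grid is stable to refinement (mean changes < 1e-3
against a 4,001-point grid). A correlation is called **reliable** when
the 95% CrI excludes zero or the directional certainty
`max(P(ρ>0), P(ρ<0))` exceeds 0.90. Reversed-scored instruments are
handled by an explicit per-instrument orientation field so correlations
are reported in the conventionally plotted direction.

Plausible-values correlations are attenuated by posterior uncertainty:
with scores built at population correlation 0.4 and realistic posterior
spread, the per-draw correlations centre below 0.4. This is inherent to
the method, not a defect; the recovery tests are written
shrinkage-aware.

**Relative importance** uses the LMG decomposition: each predictor's
share of the full-model R² is its R² increment averaged over all
predictor orderings, computed per posterior draw by exact subset
enumeration (≤ 8 predictors; shares sum to the full R² to 1e-10). Subset
R² values come from Gram-matrix identities, so the per-draw cost is a
few thousand small solves.

## Rating and score models

Bounded visual-analog ratings use **ordered beta regression**: ordered
cutpoints `c1 < c2` on the latent logistic scale split the response into
a point mass at 0 (`1 − logistic(η − c1)`), a continuous
`Beta(μφ, (1−μ)φ)` interior with `μ = logistic(η)`, and a point mass at 1
(`logistic(η − c2)`). The task-rating model regresses η on group ×
condition cell means plus participant random intercepts with
group-specific SDs, fit by the same blocked adaptive MCMC machinery
(cell effects and intercepts are conditionally independent blocks);
predicted cell means on the response scale are the analytic mixture mean
at the population-level intercept (zero). Priors: Normal(0, 5) on cell
effects and cutpoints (ordering enforced by rejection), Exponential(0.1)
on φ, half-Normal(0, 1) on intercept SDs.

Unbounded outcomes (age, momentary-fatigue change scores) use a Gaussian
model with unequal group variances. Under the noninformative prior
`p(μ, σ²) ∝ 1/σ²` the posterior is conjugate (scaled inverse-χ² for σ²,
normal for μ | σ²), so draws are exact Monte Carlo rather than MCMC.

Questionnaire totals rescale to [0, 1] by their constructed ranges:
EAS/60, HHQ/100, SSQ12/10, and FAS as `(score − 10)/30` — the FAS is the
sum of 10 items each scored 1–5, so its floor is 10 even though a 0–40
range is sometimes quoted; the rescaling uses the constructed range so
the round trip is exact.

## Problem sizes and numerical choices

The recovery experiments run 15 participants per group × 168 trials
(5,040 observations) with 2 chains × (500 warmup + 500 sampling) and 14
sweeps per retained draw — a scaled-down version of the full study
(which the generator can also produce: 49 participants, 8,064
observations) sized so a full simulate-fit-summarise cycle completes in
minutes on a single core. Rating-model recovery uses 25 participants per
group and 20 replicates. HDI mass defaults to 0.95 everywhere; the
ρ-posterior grid to 2,001 points; quadratures of defective densities
split the integral at t = 50 s because the no-finish-adjacent tail decays
only algebraically.

## Known limitations

* The sampler's specialised ridge moves target this model's geometry;
  exotic configurations (e.g. very low accuracy, or deadlines cutting
  deep into the RT distribution) may need longer warmup or larger `thin`.
* Group-level structural means (`A`, `k`, `t0`) are the slowest-mixing
  quantities; at the default desk-scale settings their split R-hat is
  typically at or just below 1.01–1.02 where drift-related parameters sit
  at 1.00.
* The shared-structural variant is systematically biased low for `t0`
  when the data contain true individual variation (see above).
* `fit_rating_model` fits one question at a time; multi-question models
  with shared participant effects are out of scope.
* No model comparison (WAIC/LOO) is provided; the analysis this package
  implements performs none.
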