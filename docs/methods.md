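# Methods

## The generative model

`freeassoc` models a single free-association trial — a participant sees a
cue and types the first acceptable association — as a semi-Markov process
(SMP) with two interacting mechanisms:

**Generation.** Given a cue's empirical association norms (typicality
pTP_i = proportion of respondents endorsing association *i*), a candidate is
sampled from the tempered distribution

    P(A_i) = pTP_i^exp(β) / Σ_j pTP_j^exp(β).

β is a participant-level parameter: β = 0 reproduces the norms, β < 0
flattens them (less-constrained associative maps, the hypothesized
signature of disorganized thinking), β > 0 sharpens them.  The exp(β)
parameterization keeps the exponent positive and makes β unconstrained.

**Regulation.** A sampled candidate is accepted (and reported) with
probability

    logistic(10 · (MX(pTP)_i − α_I))          if α_sign = +1
    logistic(10 · (MX(1 − pTP)_i − α_I))      if α_sign = −1,

where MX is a per-cue min–max transform of the typicalities.  α_I ∈ [0, 1]
sets how much is rejected, α_sign whether atypical (+1) or typical (−1)
candidates are suppressed.  The logistic slope is the fixed constant 10,
not a free parameter (a free slope is not recoverable).  A rejected
candidate is resampled from scratch — the process is memoryless, which is
what gives the first-passage time its geometric/transform-domain structure.

**Timing.** Each sampled candidate costs a gamma-distributed generation
time with mean μ_i = exp(s_μ) · (−log P(A_i)) (weaker associations are
slower; a sure association costs nothing) and standard deviation
σ_i = λ·μ_i.  The trial RT is the sum of all candidates' times plus a
uniform non-decision time on [τ0, τ0 + τr].  Seven free parameters per
participant in total: β, α_I, α_sign, s_μ, λ, τ0, τr.

## The joint density and its numerics

In transform space the joint density of (reported association j, total
generation time) is

    L_j(s) = P_j · acc_j · G_j(s) / (1 − Σ_i P_i (1 − acc_i) G_i(s)),

with G_i the gamma transform.  We evaluate this characteristic function at
s = iω on a uniform frequency grid and invert it with a real FFT; the
uniform non-decision window is then applied analytically as a CDF
difference divided by τr.  Numerical choices:

- `trial_joint_density` (the reference-quality density) uses an 8192-point
  grid; the batched likelihood path (`freeassoc.fitting`) uses 128 points
  per setting with a per-setting grid extent chosen from Wald-style
  moment bounds (mean + 12 sd of the compound total time, also covering
  the observed RT).  The coarse grid costs ≲0.03 nats per trial relative
  to the dense grid, which is negligible against importance-weight noise.
- Densities are clipped at 0 after inversion (FFT ringing), and
  log-densities are floored at −745 so that a single impossible trial
  (e.g. RT below a candidate τ0) cannot zero out a participant's
  importance weight.
- FFT inversion has a noise floor relative to the density peak (machine
  epsilon times accumulated rounding), which would silently over-state
  the density of near-impossible trials — and thereby bias likelihood
  comparisons toward whichever model has more such trials.  The
  zero-rejection path (one gamma time composed with the uniform window)
  is therefore computed exactly as a gamma-CDF difference in log space,
  with a lower-tail series where the CDFs underflow: for the no-rejection
  variant this analytic form *is* the density (no FFT at all); for the
  full model it replaces any FFT value below its credible noise
  threshold, as an exact lower bound on the mixture density.
- Degenerate cases: a single-association cue has a generation-time atom at
  0 (the density reduces to the non-decision uniform); an all-equal
  typicality vector min–max transforms to 0.5 everywhere (midpoint — the
  least informative choice); RT ≤ τ0 has density exactly 0.
- Monte-Carlo forward simulation is the arbiter of correctness: the
  acceptance suite checks the inverted density bin-by-bin against a
  200,000-draw histogram (3 MC standard errors) and total probability
  against 1 (±0.005).

## Hierarchical fitting

Participant parameters are fitted by iterative importance-sampling EM with
empirical group priors.  Families respect each parameter's support:
β, s_μ ~ normal; λ, τ0, τr ~ lognormal; α_I ~ beta on [0, 1];
α_sign ~ Bernoulli on {−1, +1}.  Per iteration, each participant receives
their own draw of parameter settings from the current priors (1,000 by
default); settings are weighted by the participant's joint trial
likelihood; every family is refit by weighted moment matching pooled over
participants (with small dispersion floors keeping priors proper).
Iterations stop when the integrated BIC,

    iBIC = −2 Σ_s log( (1/K) Σ_k exp(ℓ_{s,k}) ) + H · ln(N_trials),

ceases to decrease, or at an iteration cap (default 15).  H counts group
hyperparameters (13 for the full model, 10 for the no-rejection variant,
12 for fixed-sign); the sample-size term counts trials.  The prior reported
is the one with the lowest iBIC along the trace.  Final participant
estimates are likelihood-weighted means over one large sample of settings
(10,000 by default) shared across participants, so that individual
differences are not driven by sampling variation; the weighted mean of
α_sign in [−1, 1] is thresholded at 0 for the discrete estimate and kept
as `alpha_sign_mean` for diagnostics.  The τ0 prior is initialized below
the cohort's minimum RT, since non-decision time cannot exceed any
observed RT and participants differ widely in their minimum.

Model variants: `no_rejection` removes the acceptance stage (every
candidate reported), `fixed_sign` clamps α_sign to +1.

## Synthetic data

The generator emulates the study conditions the analysis assumes: a
148-cue pool with 20 cues per participant (the main-study design), per-cue
typicality norms with rank-r weight r^−skew normalized to 1 (skew 1.0 by
default — a Zipf-like stand-in, since the empirical shape of per-cue
typicality distributions is not known), cohorts drawn from group priors
with realistic heterogeneity (RTs of a few seconds, a mix of regulation
directions), trials simulated by running the generative process forward,
and two-prompt narrative corpora built as topical random walks over a
clustered unit-vector embedding space (per-step drift probability of
redrawing the topic uniformly).  Ground truth (true parameters, latent
rejection counts) lives in sidecar tables the fitting code never sees.
One global seed expands into fixed per-component child streams.

What the generator does **not** emulate: color stimuli themselves (cues
are opaque ids), real norms' heterogeneity across cues (every synthetic
cue shares the same typicality shape), response-signal manipulations,
misspellings/typing dynamics, and natural-language semantics (narrative
"words" are cluster members, not English).  Passing recovery and metric
tests therefore shows the algorithms are correct and informative under the
assumed structure — not that real human data satisfy that structure.

## Desk-scale experiment configurations

Full-scale fitting (1,000 settings × up to 15 iterations, 10,000 final
settings) is the default for real use.  The packaged experiments use
reduced problem sizes chosen as the package's own desk-scale standard:

- **Recovery** (`run_recovery_experiment`): 60 participants × 30 trials,
  60-cue pool, 8 associations/cue, 300 settings/iteration, ≤6 iterations,
  1,500 shared final settings.  Reported: Pearson r(true, estimated) per
  parameter, α_sign accuracy (overall and among strong regulators,
  true α_I ≥ 0.6), and the iBIC trace.
- **Model comparison** (`run_model_comparison`): 100 participants × 20
  trials simulated under heavy rejection (α_I ~ Beta(16, 4), mean 0.8;
  α_sign = +1), both variants fitted with 300 settings/iteration, ≤12
  iterations.  The compared iBIC is then evaluated for each variant's best
  prior with a common 1,000-sample evidence estimate, so that the two
  variants' marginal likelihoods carry equal estimator precision
  regardless of their dimensionality.

## Narrative metrics

- **TF-IDF typicality**: smoothed IDF ln((1+N)/(1+df)) + 1, L2-normalized
  vectors, cosine similarity; a document's score is its mean similarity to
  every other same-prompt document (focal excluded).  Unseen-in-others
  vocabularies score 0; identical documents score 1.
- **Relaxed word mover's distance**: mean nearest-neighbor Euclidean
  distance from each word of one window to the other window, symmetrized
  by averaging both directions.  Full optimal transport (uniform weights,
  solved by linear programming) is available behind a flag; the relaxation
  lower-bounds it.  Coherence negates the distance so that higher is
  always more coherent ("inverse" as negation, not reciprocal — linear and
  stable near zero).
- **Windowed coherence**: for each starting offset 0..w−1, consecutive
  non-overlapping windows of w lemmas are compared (cosine of mean vectors
  or negated relaxed WMD), averaged over pairs then offsets.  A document
  shorter than 2w is unscoreable at that window.
- **Composites**: each measure is z-scored within prompt across
  participants and summed across prompts; first-/second-half typicality
  splits each document at its midpoint and scores halves against same-half
  corpora (a drifting second half lowers second-half typicality).

## Known limitations

- The EM is importance sampling from the prior; with 7 parameters and
  hundreds of settings per participant the evidence estimate is noisy and
  downward-biased, so iBIC comparisons between variants of different
  dimensionality need the sample sizes noted above.
- Moment-matching M-steps can collapse prior dispersion on small cohorts;
  the dispersion floors bound but do not remove this.
- τ0 and τr recover weakly at 20–30 trials per participant (their
  likelihood contribution is a narrow uniform window); β, s_μ, α_I and
  α_sign are the parameters the recovery suite certifies.
- Unseen response lemmas are given smoothed typicality 1/(n_respondents+1)
  and appended to the candidate set, so held-out data never has zero
  probability; norms are built once from all participants (the focal
  participant is not jackknifed out).
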