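# Methods note

This note documents the model implemented by `perceptlearn`, the
assumptions behind it, the synthetic data generator, and the numerical
choices. Nothing here is an empirical claim about human data; every
number the package reports is computed from synthetic cohorts that the
package itself generates.

## Scientific problem

When a bistable stimulus (a structure-from-motion sphere that can be seen
rotating leftward or rightward) is viewed without disambiguating depth
cues, perception must rely on prior expectations. If an arbitrary cue (a
high or low tone) is probabilistically coupled to the rotation direction,
and that coupling reverses repeatedly within a session, observers can
learn and re-learn the association quickly — and their percepts on
ambiguous trials are biased toward what they have learned. The package
models this situation end to end: the task, the trial-by-trial learning,
the percept formation, and the recovery of each observer's weighting of
the different expectation sources from their responses.

## Task design

A session has 576 trials in 6 runs of 96. Trials come in blocks of 16,
24 or 32; within each block exactly 75% of trials are unambiguous stimuli
whose rotation is *congruent* with the block's tone–rotation association,
12.5% are unambiguous *incongruent* stimuli, and 12.5% are ambiguous test
trials. The association (high tone → leftward vs. high tone → rightward)
alternates between consecutive blocks, so the objective contingency is
75% and reverses every block. Blocks never straddle run boundaries.
Trial order within a block is randomized under one constraint: every
ambiguous test trial is preceded by at least three consecutive congruent
unambiguous trials, so that test percepts probe a freshly confirmed
expectation. The generator rejection-samples orderings until the
constraint holds (cap 10,000 attempts per block; in practice a handful
suffice) and a separate validator re-checks every published constraint on
any sequence, generated or loaded.

## Learning model: three-level binary hierarchical Gaussian filter

The observer learns the tone–rotation contingency with a binary
hierarchical Gaussian filter. The input on each unambiguous trial is

- u = 1 for (high tone, leftward) and (low tone, rightward),
- u = 0 otherwise,

i.e. the filter tracks the *contingency*, not the rotation itself.
Level 1 is the binary input; level 2 a Gaussian tendency x2 with
logistic link, prediction `mu1hat = logistic(mu2 + rho2)`; level 3 a
Gaussian volatility x3 that sets level 2's effective learning rate
through `exp(kappa2*mu3 + omega2)`. The update equations are the
standard variational inversion of this generative model (precision-
weighted prediction errors at each level). Ambiguous trials carry no
sensory evidence about the contingency; by default the filter receives
no input and only inflates its predictive variance (policy `skip`), with
an alternative policy that feeds back the observer's own percept
(`percept-coded`).

Fixed parameters (exposed, not fitted by default):

| parameter | default | meaning |
|---|---|---|
| `mu2_0`, `mu3_0` | 0 | neutral initial beliefs |
| `sigma2_0` | 0.1 | initial level-2 variance |
| `sigma3_0` | 1.0 | initial level-3 variance |
| `rho2` | 0 | no drift |
| `kappa2` | 1 | unit volatility coupling |
| `omega2` | −2.28 | baseline level-2 learning rate |
| `omega3` | −6.14 | baseline volatility of volatility |

`omega2`/`omega3` defaults are ideal-observer values for this reversal
schedule (obtained by minimizing the filter's cumulative surprise on the
task; `bayes_optimal_fit` reproduces this calibration). An alternative
model variant frees them per subject with Gaussian priors
(−2.28, 1) and (−6.13, 1) on the native scale — a log-normal prior is
impossible for negative-valued parameters.

## Observer model

On each trial the observer combines up to three prior expectations about
the rotation direction (coded right = 1, left = 0):

- **Association** (precision `pi_a`): the HGF's current contingency
  prediction, mapped through the tone — `mu_a = mu1hat` for a low tone
  and `1 − mu1hat` for a high tone.
- **Priming** (precision `pi_p`): the percept on the most recent
  unambiguous trial (incorrectly reported trials are excluded).
- **Memory** (precision `pi_s`): the percept on the most recent
  *ambiguous* trial.

These are fused by precision weighting into a single prior
(`mu_prior`, `pi_prior`); fusing sequentially or jointly is
algebraically identical and the tests assert it. The stimulus
contributes a stereo-cue mean `mu_stereo` (1 for rightward unambiguous,
0 for leftward, 0.5 for ambiguous) with precision `pi_stereo`, fused the
same way into (`mu_m`, `pi_m`). The posterior probability of a
rightward percept is

    P(rightward) = logistic((2*mu_m − 1) * c),   c = pi_m by default,

which is 0.5 exactly when prior and evidence balance and sharpens with
total precision. The constant `c` is exposed (`mode_weight`) because the
mapping from fused precision to the steepness of the two-mode likelihood
trade-off is a modeling choice; the default identifies it with `pi_m`.
The response model is a unit-square sigmoid with temperature `zeta`
(default 1).

Default precisions `pi_a = pi_p = pi_s = 0.5`, `pi_stereo = 2.5`: weak
expectation sources against a strong but not deterministic stereo cue,
matching the scale of the inversion priors below.

## Inversion and model comparison

Each subject is fitted by MAP estimation of the log precisions
(log-normal priors: mean log 0.5, sd 1 for `pi_a`, `pi_p`, `pi_s`; mean
log 2.5, sd 1 for `pi_stereo`), using multistart BFGS (5 starts). Model
evidence is approximated by the Laplace approximation at the MAP —
`log p(y|m) ≈ −NLJ + (d/2)·log 2π − ½·log det H` with `H` the central-
difference Hessian (step 1e−4). The model space crosses the three
expectation sources on/off (2³ = 8 models, labels like `+A−P+S`);
excluded sources are structurally pinned at zero precision, and
`pi_stereo` is always free.

Group-level comparison uses random-effects Bayesian model selection: a
variational Dirichlet scheme over model frequencies (uniform prior
`alpha0 = 1`, tolerance 1e−6), with exceedance probabilities estimated
by Dirichlet Monte Carlo (default 10⁶ draws; a warning is raised below
10⁴). The K = 2 case is cross-checked against the closed-form Beta tail
probability in the tests.

## Behavioral metrics

For each expectation source, the perceptual bias on ambiguous trials is

    bias = 100 · (n_congruent − n_incongruent) / (n_congruent + n_incongruent)

where congruency is between the percept and that source's expected
direction; trials where the source is undefined (e.g. no preceding
unambiguous trial) are dropped, as are unambiguous trials with missing
or incorrect responses when building the expectation history. A
high-confidence variant restricts to confidence level 4. Motor
adaptation on unambiguous trials is
`(meanRT_congruent − meanRT_incongruent) / meanRT_all` (unitless;
negative = faster on congruent trials). Bias–parameter relationships
use Pearson correlation with pairwise NaN dropping.

## Synthetic data generator

Because the original behavioral data are not available, the package
validates itself on synthetic cohorts. The generator emulates:

- observers that use all three expectation sources with the default
  precisions, with log-normal between-subject heterogeneity
  (sd 0.5 for the qualitative cohort; sd 1.0 — matching the inversion
  prior — for the parameter/model recovery suites);
- response times drawn log-normally (median 0.625 s, log-sd 0.2) with a
  multiplicative speed-up (×0.95) on association-congruent unambiguous
  trials, yielding roughly −5% normalized motor adaptation;
- 4-point confidence ratings with P(level 4) = 0.85 on unambiguous and
  0.75 on ambiguous trials.

It does **not** emulate: lapses or attention fluctuations, response
omissions, learning of the RT or confidence processes, eye-movement or
depth-cue artifacts, or any within-session drift of the precisions.
Percepts feed back into the priors sequentially during simulation, so
simulated histories are self-consistent.

## Numerical choices

- All randomness flows from explicit seeds; one global seed fans out to
  per-stage and per-subject seeds via `numpy.random.SeedSequence`
  (values kept below 2³¹), so every artifact is regenerable
  bit-identically.
- The HGF filter guards `exp` overflow (raising a typed numerical error
  that optimizers treat as an infinite objective) and probabilities are
  clamped at 1e−12 before logs.
- The likelihood of a whole session factorizes over trials once the HGF
  trajectory is fixed; since the trajectory depends only on
  (`omega2`, `omega3`), it is cached per subject and the per-model
  likelihood is evaluated vectorized. This makes the 8-model fit of one
  subject take well under a second.
- CSV round-trips use 17-significant-digit floats and pandas'
  `float_precision="round_trip"` parser so written cohorts reload
  bit-identically.

## Open design decisions

- The mode-weighting constant in the perceptual posterior is identified
  with the fused precision `pi_m`; the `mode_weight` hook allows other
  choices.
- On ambiguous trials the contingency filter receives no input by
  default (`skip`); the `percept-coded` policy is available but changes
  the learning dynamics and is off by default.
- The Laplace approximation stands in for the variational negative free
  energy; for these smooth, low-dimensional posteriors the two agree
  closely, and only evidence *differences* enter model selection.

## Limitations

- All quantitative performance figures (recovery correlations, model
  recovery rates) are properties of the synthetic generator settings,
  not of human data.
- `omega3` is weakly identified by 576 binary trials; volatility-related
  individual differences load mostly on `omega2`.
- The Laplace evidence can be biased when the MAP sits near a parameter
  boundary (very small precisions); the fitter reports the Hessian's
  condition number so such fits can be screened.
- Single-CPU only; a full 31-subject, 8-model analysis takes on the
  order of a minute, so no parallel execution is provided.
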