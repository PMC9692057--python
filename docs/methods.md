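# Methods

## State space and priors over worlds

A world is a set of five *distinct* integer stick lengths from 1″ to 9″,
giving C(9,5) = 126 states enumerated exactly (lexicographically, for
bit-reproducible reductions).  Distinctness is a substantive modelling
choice, not a convenience: with repetition-allowed worlds the two
properties that anchor the model both fail — the β = 0 pragmatic
listener no longer coincides with the literal listener (the speaker
chooses among five stick *tokens*, so repeated lengths get multiplicity
weight that δ-conditioning lacks), and an 8″ stick never backfires at
any bias (observing the maximum-length token still leaves many long
worlds).  With distinct sticks both hold exactly.  The prior over
worlds is uniform.

Worlds whose mean is exactly at the 5″ midpoint are excluded when
marginalising to the binary verdict, so the prior belief in "longer" is
exactly 0.5 by the mirror symmetry of the world prior.  That symmetry
also gives `P(longer | u, shorter-agenda) = 1 − P(longer | 10−u,
longer-agenda)`, which the vectorised likelihood uses and the tests
verify against direct enumeration.

## Listener and speaker models

* **Literal listener** `L0(w|u) ∝ δ_u(w) P(w)`: conditions only on the
  revealed stick being one of the five.  A semantic noise floor ε is
  supported for generality but fixed to 0 in-task, since the speaker
  can only reveal actual sticks.
* **Motivated speaker** `S(u|w, w*, β) ∝ L0(w*|u)^β` over the world's
  five sticks.  Because only true utterances are available, the
  epistemic utility term is constant and the soft-max temperature α is
  not separately identifiable; the product α·β is treated as the single
  parameter β (α ≡ 1).
* **Pragmatic listener** `L1(w|u, w*, β) ∝ S(u|w, w*, β) P(w)` by full
  enumeration.  The verdict marginal is assembled entirely in log space
  so that extreme biases (checked at β = 10⁶) never underflow.

The persuasive utility `ln L0(w*|u)` is strictly monotone in stick
length for each agenda; the weak evidence effect of evidence u for
agenda w* is the prior belief (0.5) minus the pragmatic posterior
belief in w*, positive values meaning the evidence backfired.

## Response model

Beliefs map to the 0–100 slider as `100 · clip(p_longer + offset, 0, 1)`
and responses are Gaussian on the probability scale with a free shared
`noise_sd`.  The response distribution family and the order of offset
and clipping are repo choices — a Gaussian slider likelihood is the
conventional default and keeps all six variants on the same footing.
Latent group assignments in every mixture variant are marginalised
analytically; nothing is sampled per participant.  The likelihood is
evaluated two ways — a scalar per-record path and a vectorised
evaluator used by the samplers — and the suite asserts they agree to
1e-10 on every variant.

The speaker-dependent variant keys its mixture weights by the raw
rank-1 stick choice (five keys, `w_2 … w_9`); the binary
strongest-expected vs other grouping is derived for reporting.

## Synthetic participants

The generator reproduces the experiment's structure: contestant order
counterbalanced exactly 50/50 and shared across phases; first evidence
drawn from {6,7,8,9} (long-biased first) or {4,3,2,1} (short-biased
first) with the weak values {4, 6} oversampled 3:1 (they carry the
theoretically critical conditions; the ratio is a repo choice), giving
four strength conditions.  Defaults: n = 723 participants,
67% pragmatic types, generating bias β = 2.26, response offset −0.13
and response noise sd 0.1 on the probability scale (the noise level is
a repo choice; slider data rarely do better than ±10 points).

Pragmatic types rank the example sticks {2,4,7,8,9} by persuasive
utility (9 first for the long-biased contestant, 2 for the short-biased
one) and answer the listener phase as J1 at the generating bias.
Literal types answer as J0 and *hedge* in the speaker phase.  Their
hedging policy is a stand-in — the empirical distribution of
non-strongest choices is unknown — and defaults to a uniform choice
among the interior sticks {4, 7, 8}: this keeps the strongest-expected
group share at exactly the pragmatic share (67/33) and the sub-groups
type-pure.  `uniform` (all five sticks) and `non-strongest` policies
are available in the config.

What the generator deliberately does not emulate: second-evidence
presentations and order effects, attention-check exclusions (n is
post-exclusion), free-response text, and any participant-level
heterogeneity in β, offset or noise.  Passing recovery tests therefore
shows the pipeline is self-consistent under these idealised conditions,
not that real data meet them.

## Inference

Priors: β ~ Uniform(0, 10); offset ~ Uniform(−0.5, 0.5); noise_sd ~
HalfNormal(0.3); mixture weights ~ Uniform(0, 1); MAS anchor R ~
Uniform(−1, 1); η ~ Uniform(0, 1).  All are repo choices except the MAS
anchor support.

**Sampler.** Random-walk Metropolis, four chains, 1,000 kept draws
total, burn-in 7,500 and thinning lag 100 per chain by default.
Sampling happens in unconstrained space (logit transforms for bounded
parameters, log for the noise sd, with Jacobians), because mixture
weights hug their boundaries and a bounded random walk mixes poorly
there.  During burn-in only, the proposal adapts continuously
(Robbins–Monro): a global log step size targets ≈0.3 acceptance while
the proposal covariance tracks the chain's recursive empirical
covariance; the proposal is frozen afterwards, so kept draws come from
a valid Markov chain.  Split-R̂ is computed per parameter (via arviz)
and values above 1.1 are reported as warnings, not errors.

**Point estimates.** MAP (or maximum likelihood) by multi-start
L-BFGS-B within the prior bounds, eight prior-drawn starts by default
plus optional user-supplied starts; deterministic given the seed.

**Model comparison.** WAIC is implemented directly on the deviance
scale, `−2·Σ(lppd_i − p_i)` with `p_i` the per-observation posterior
variance of the log-likelihood (warning at p_i > 0.4); its standard
error uses the ddof-1 spread of per-observation contributions.
PSIS-LOO uses arviz's generalised-Pareto smoothing of the importance
weights and flags observations with k̂ > 0.7; with a degenerate
(constant-draw) posterior both criteria reduce exactly to −2·lppd.
Both are cross-checked against arviz's reference implementations and
against exact leave-one-out refits of a conjugate normal model in the
tests.  k-fold cross-validation partitions participants with a seeded
permutation and reports per-fold MAP fits.

## Numerical and design notes

* Determinism: every stochastic operation takes an explicit seed
  (default 1); chain seeds are spawned from it.  Reruns are bit-identical.
* Mixture log-likelihoods use log-sum-exp; zero weights contribute
  exactly nothing (no −inf arithmetic leaks).
* Evidence strength s(u) = (u − 5)/4 is the minimal linear map onto the
  MAS prior support [−1, 1]; out-of-range AA updates are clipped rather
  than squashed, since the update rule is additive and no link function
  is implied.
* Degenerate inputs: empty participant tables, all-invalid CSV rows and
  unknown variant labels raise; rows violating record invariants are
  rejected and logged with their line numbers.

## Known limitations

* With the default response noise (sd 0.1), the J0 and J1 predictions
  differ by only 0.05–0.09 probability across the evidence range, so
  the mixture weights of the type-pure sub-groups sit on a flat
  likelihood ridge with β: point estimates of a weight whose true value
  is 1 land in the interior (0.7–1.0) in a sizeable fraction of
  replicated experiments at n = 723, and β point estimates drift
  correspondingly high, even though the 95% posterior interval for β
  covers the generating value with the advertised frequency.  This is a
  property of the design's statistical information, not of the
  optimiser or sampler (verified by starting both at the generating
  values).
* The Gaussian slider likelihood ignores the clipping the generator
  applies at the scale bounds; with predictions near 0 or 100 this
  mildly biases fits.
* The full posterior pipeline costs a few minutes per variant at the
  default sampler settings; the bundled tests use shorter chains for
  replicated-coverage checks (burn-in 800, thinning 5), which is enough
  for interval coverage but not for publication-grade R̂.
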