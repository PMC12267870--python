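# Methods

## The model

A lexical-decision response time is decomposed into a deterministic,
participant-specific shift and a stochastic component:

    Y_ijkl = theta_j + X_ijkl,

where `j` indexes the participant, `k` the word-frequency band, `l` the
word length and `i` the trial.  `theta_j` (ms) is the participant's
nondecision time — encoding plus motor execution, the irreducible minimum
of an RT — and is assumed independent of item properties.  `X_ijkl > 0`
carries all item effects and follows one of three positively skewed
two-parameter families, evaluated at the residual `y - theta_j`:

| family    | rho[1]            | rho[2]             | E[X]                  |
|-----------|-------------------|--------------------|-----------------------|
| lognormal | mu (ln-ms)        | sigma^2            | exp(mu + sigma^2/2)   |
| Wald      | mu (mean, ms)     | lambda (shape, ms) | mu                    |
| gamma     | alpha (shape)     | beta (rate, 1/ms)  | alpha / beta          |

Each (participant, band, length) cell has its own `rho_jkl`; no
functional form is imposed on how the parameters scale with frequency or
length — the banding is the point: it lets the data trace out that
scaling nonparametrically.

The hierarchy places gamma priors on everything positive:

* `rho_jkl[m] ~ Gamma(alpha_l[m], beta_l[m])`, with separate pairs per
  word length `l`, so lengths can differ systematically;
* `theta_j ~ Gamma(alpha_theta, beta_theta)`;
* every hyperparameter `phi_i` in `psi = {alpha_l[1], beta_l[1],
  alpha_l[2], beta_l[2]}_l ∪ {alpha_theta, beta_theta}` gets a fixed
  `Gamma(a_i, b_i)` hyperprior.  With the full 4-10 character range psi
  has 30 entries.

All times are in milliseconds.  This matters for the lognormal: its
location `mu = E[ln X]` must be positive for the gamma prior to make
sense, which holds when typical residuals exceed 1 — true in ms, false in
seconds.

**Default hyperprior pairs.** `a_i = b_i = 0.1` for every entry
(hyperprior mean 1, variance 10).  These are deliberately diffuse: with
tens of cells per length the likelihood dominates, and the shift prior in
particular stays close to uninformative so `theta_j` is determined by the
data.  All pairs are configurable per entry through `PriorConfig`.

## Preprocessing

The trial filters reproduce the standard megastudy preparation, in this
order, and only ever exclude *participants*, never individual trials:

1. flagged archive files are dropped by name;
2. participants with overall accuracy below 60% are removed (accuracy is
   computed over all trials, words and nonwords, before nonwords are
   discarded — the rule runs on the raw archive);
3. participants whose share of RTs outside [150, 2000] ms exceeds 20%
   (strictly) are removed.

Word trials are then merged with the lexicon (word-form frequency WF and
the contextual-diversity measures DCD/UCD), keeping 4-10 character words
with a positive occurrence value and an admissible part of speech.

**Frequency bands.**  Band boundaries are the (m/k)-quantiles (linear
interpolation) of the *trial-level* occurrence values, so frequent words
weigh in by their observation counts.  A value equal to a boundary
belongs to the lower band, making band membership a function of the
occurrence value (no value can sit in two bands, whatever the ties).  The
band count k is the largest for which every band keeps at least
`min_count` observations after the tie rule (default floor 40,000
observations per band, matching megastudy practice; the floor is
configurable and desk-scale runs lower it).  The floor-based rule is one
deliberate resolution of an under-determined choice: with ~778k
observations a 40k floor admits any k up to 19, and the exact rule used
to land on a specific k for the reference datasets is not recoverable;
maximizing k extracts the finest frequency resolution the floor allows.

## Posterior sampling

The sampler is an adaptive Metropolis-within-Gibbs scheme written for
this model's geometry (vectorized numpy; no trial-level Python loops):

* **theta block** — per-participant Gaussian random walks on the natural
  scale.  The likelihood is `-inf` at `theta_j >=` the participant's
  minimum RT, so the posterior support constraint is enforced by
  rejection.
* **shift-rescale block** — `theta_j` and the cell locations lie on a
  narrow ridge: raising the shift must shrink the stochastic component.
  A second proposal moves `theta_j` and simultaneously remaps every cell
  of that participant by its maximum-likelihood response, computed from
  observed per-cell statistics only (mean log-residual and its variance
  for the lognormal; mean residual and the inverse-residual statistic for
  the Wald; the log-moment gap for the gamma).  Because the remap is a
  deterministic diffeomorphism in (theta, theta'), the reverse proposal
  is its exact inverse and the Jacobian enters the acceptance ratio; the
  kernel is exact, not approximate.  Without this move the joint
  relaxation time at realistic trial counts is thousands of iterations;
  with it the shift mixes in tens.
* **rho block** — per-cell log-scale random walks: each component alone,
  plus a coupled move (same direction for gamma and Wald, whose two
  parameters are strongly correlated; independent for the lognormal).
  Each sub-move has its own adapted scale, because e.g. the lognormal mu
  and sigma^2 need step sizes an order of magnitude apart.
* **psi block** — the rate hyperparameters are conditionally conjugate
  (`beta | alpha, rho ~ Gamma(a + n alpha, b + sum rho)`) and are drawn
  exactly; the shapes take log-scale random-walk steps; a coupled
  `(alpha, beta) -> (alpha, beta) * exp(eps)` move travels the
  mean-preserving ridge that one-at-a-time updates cannot.  Two psi
  sweeps run per iteration (they touch no trial-level likelihood and are
  essentially free).

Step sizes adapt in batches of 25 during warmup only (targets 0.44 for
scalar moves, 0.35 for paired moves), so the post-warmup chain is a valid
Markov chain.  Chains are initialized from jittered method-of-moments
estimates at an overdispersed random shift.  Split-chain R-hat and bulk
ESS are computed for every scalar quantity via arviz; any R-hat above
1.01 raises a warning and is flagged in the metadata, with draws still
returned.

Correctness is established two ways: on a low-dimensional instance
(1 participant, 2 gamma cells, 20 trials, fixed psi) the posterior
moments agree with dense-grid quadrature written directly from the
density formulas; and with no data at all the sampler reproduces the
forward-simulated prior of the full hierarchy.

## Assessment and model selection

**Posterior predictive p-values.**  Replicated datasets are drawn by
picking a joint posterior draw and sampling every cell at that draw's
parameters, preserving cell sizes.  For the mean statistic,
`ppp = #{r : mean(rep_r) >= mean(obs)} / R` per cell; ties count toward
the numerator (conservative toward 0.5 under discreteness).  Values near
0.5 indicate fit.  Cell-level granularity is the default (participant
level is available) — the finest unit consistent with the stratification.

**elpd.**  The expected log pointwise predictive density is approximated
by Pareto-smoothed importance-sampling leave-one-out (arviz), with WAIC
and the in-sample log pointwise predictive density (`lpd`, computed
in-package by log-mean-exp over draws) as cross-checks; points with
Pareto k > 0.7 are flagged.  Models are ranked against the best
(largest-elpd) model: the reference shows `delta = 0, se = 0`; the others
report `delta = elpd_m - elpd_ref` and the paired standard error
`sqrt(n) * sd(pointwise differences)`.

## The synthetic-data generator

The generator emulates the structure, not the linguistics, of megastudy
archives: random letter strings with Zipf-distributed occurrence values
(`value ∝ rank^-s`, default s = 1), three measures (WF, DCD, UCD) coupled
through a Gaussian copula at rank correlation 0.9, and trials produced by
the generative model itself — `theta_j* ~ Gamma(25, 0.1)` (mean 250 ms,
sd 50 ms, matching reported nondecision times), `rho_jkl*` from the
length-specific priors at a fixed psi*, RTs from the chosen family.
Default stochastic components centre near 230-250 ms (lognormal mu about
5.45 with a +0.03-per-character length trend, sigma^2 about 0.16),
giving realistic 400-600 ms total RTs.  Accuracy flags are Bernoulli(0.95);
nonword fillers are off by default and only exercise preprocessing.  An
optional `band_gradient` scales cell means down across bands to emulate
the word-frequency effect when a monotone truth is needed.

The default design — 20 participants x 4 bands x 3 lengths x 50
trials/cell, 12,000 trials — is a deliberate desk-scale version of the
megastudy conditions (hundreds of participants, ~7 x 10^5 trials),
chosen so a full fit-assess-compare cycle runs in minutes.  What passing
tests show, and what they do not: recovery and calibration at this scale
demonstrate that the machinery is correct and well-calibrated for data
generated by the model; they do not show that real lexical-decision RTs
are lognormal, that contextual diversity beats word-form frequency, or
that the filters' empirical exclusion counts on the actual archives are
reproduced — those claims need the archives themselves.  Family
discrimination in particular is data-hungry: a shifted Wald mimics a
shifted lognormal closely at sigma^2 ≈ 0.16, so the family-recovery check
uses ~10^4 trials per repeat and still treats within-se ties as expected
behaviour.

## Numerical choices and edge cases

* Density at `y == theta` is 0 (log-density `-inf`), the limit from the
  right, keeping log-likelihoods finite-or-`-inf`, never NaN.
* rho parameters are proposed on the log scale internally; the public
  surface reports natural-scale values only.
* Posterior medians use numpy's midpoint convention for even draw counts.
* Cells below 5 trials (configurable) are modelled as usual — the
  hierarchy shrinks them — but listed in the fit metadata.
* Degenerate cells (a single trial, or zero residual variance) fall back
  to the location-only remap in the shift-rescale move.
* The band-dependent shift `theta_jk` is accepted as a constructor flag
  for forward compatibility but not implemented.
* Empty-band and all-tied banding inputs collapse to a single band with a
  warning rather than erroring.

## Known limitations

* The sampler is exact but random-walk based; very small cells with
  near-boundary shifts mix more slowly than gradient-based samplers
  would.  Diagnostics surface this rather than hiding it.
* In-sample `lpd` is optimistic relative to LOO and is intended as a
  cross-check, not a selection criterion.
* The generator's words carry no orthographic or semantic structure;
  preprocessing paths that depend on real spelling conventions (e.g.
  British/American variants) are out of scope.
* Accuracy-based trial weighting is not modelled: correct and incorrect
  trials enter the likelihood alike, as in the reference analysis.
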