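# Methods

## The paradigm being modelled

The Implicit Salience Paradigm (ISP) is an outcome-detection task framed to
the participant as a simple discrimination: press one button for a 10-cent
coin, another for a blue circle. Each outcome is preceded by a cue with two
binary features — color (colorful/grey) and shape (square/triangle). Exactly
one feature is *relevant*: one of its manifestations is followed by the coin
on 80% of its presentations, the other on 20%, and which manifestation is
rewarded reverses every 20-trial block. The other feature is *irrelevant*
(50/50). After 80 of the 160 trials the relevant dimension itself switches.
Learning is incidental; the behavioral readout is the reaction time to the
outcome.

The generator (`relsal.task`) reproduces this design. In its default
`exact_counts` mode every block realizes the design frequencies exactly —
8/2 coin/circle outcomes after the rewarded manifestation, 2/8 after the
non-rewarded one, a 5/5 split of each irrelevant manifestation within each
outcome type — and the trial order within a block is a seeded permutation.
This makes the printed design quantities (160 trials, 10 coins per block,
8 EUR total payout, exact 0.8/0.5 conditional frequencies) deterministic
test targets. A Bernoulli mode (`exact_counts=False`) draws cues and
outcomes independently per trial with the scheduled probabilities for
simulations that need sampling variability in the design itself. Whether
the original experiment count-balanced or sampled its blocks is not
documented; both modes are provided and the exact mode is the default
because it is the testable one. The rewarded manifestation alternates
deterministically between blocks, and the first relevant dimension is a
config flag rather than a randomized assignment, for reproducibility.
Missed responses are not simulated unless a `miss_rate` is requested.

## Learning model: a two-branch binary HGF

Each cue feature is learned by its own binary hierarchical Gaussian filter
branch. Per trial k a branch receives a binary input u(k) coding the
(manifestation, outcome) pairing of that trial; the direction of this coding
is arbitrary — beliefs track the *strength* of an association, not reward
value — and the fixed reference pairing is documented in `relsal.hgf`.
The level-2 state x2 follows a Gaussian random walk with step variance
exp(omega); its logistic transform is the outcome prediction mu1hat. The
update of the level-2 mean is the first-level prediction error
delta1 = u − mu1hat weighted by the inverse of the updated level-2
precision,

    mu2(k) = mu2(k−1) + delta1(k) / pi2(k),
    pi2(k) = 1 / (sigma2(k−1) + exp(omega)) + mu1hat(k) (1 − mu1hat(k)).

Three-level variants place a volatility state x3 above x2 (coupling kappa,
step variance exp(omega3)), modulating the level-2 step size and updated by
the standard volatility prediction-error equations. Following the model
space of the original analysis, the free learning parameters are omega and
the initial level-2 variance sigma2_0, shared by both branches; mu2_0 is
fixed at 0 (prediction 0.5). The 3-level structural constants (kappa = 1,
omega3 = −6, level-3 initial mean 1 and variance 0.1) are fixed, not
fitted — the source analysis does not publish its 3-level priors, so these
are configurable defaults, and any comparison of fitted 3-level parameters
with the original report is indicative only.

**Relevance.** The first-level precision of a branch,

    pi1hat = 1 / (mu1hat (1 − mu1hat)),

is the model's definition of the feature's subjective relevance: it is 4
when the feature predicts nothing (mu1hat = 0.5) and grows without bound as
the prediction becomes confident. The relevance *weight* of a feature is
its first-level precision normalized by the sum over both features; a
feature's irrelevance weight is the other feature's relevance weight.

**Precision feedback.** The `precfb` learning variants couple the branches:
the level-2 mean update of a branch is scaled by 2 × its relevance weight
computed from the previous trial's predictions, so beliefs about a feature
currently held irrelevant are updated less (down to not at all) and a
relevant feature up to twice as fast. The factor is normalized so that at
equal relevance (weight 0.5) the update reduces exactly to the standard
HGF update and the coupling vanishes. This is this package's concrete
reading of "relevance could affect belief updating"; the original
mechanism is described only in an unavailable supplement, so this variant
should be treated as an assumption isolated behind the `variant` flag, not
as a reproduction of the original equations. Using the *previous* trial's
weights avoids a simultaneity loop between the two branches.

Numerical guards: the logistic argument is clamped at ±36 and level-2
variance floored at 1e−12 (both counted on the returned trajectories);
a non-positive level-3 precision marks the trajectory invalid, which the
fitting layer treats as zero posterior mass.

## Response models

All four response models are linear in log reaction time,

    log rt = beta0 + beta1 * PE
             − w_color (beta2 m_colorful + beta3 m_grey)
             − w_shape (beta4 m_square + beta5 m_triangle)
             + beta6 * outcome          (circle = 1, coin = 0)
             + Gaussian noise, variance zeta,

with PE the mean of the two branches' unsigned first-level prediction
errors. The baseline model (BL) uses the plain mean and constant
manifestation biases (w = 1). RelPE weights each branch's |delta1| by its
relevance weight inside the mean (the printed /2 divisor is kept even
though the weights sum to one). IrrelBias scales each feature's
manifestation-bias term by the feature's irrelevance weight — an
idiosyncratic preference for one of two manifestations matters most when
the feature is believed uninformative, the model-level formalization of
aberrant salience. The full model applies both. Crossed with the four
learning variants this gives the 16-model space.

Because m_colorful + m_grey = 1 (and likewise for shape), beta2..beta5
trade off against the intercept: only within-feature differences are
identified. No hard sum-to-zero constraint is imposed; instead the
zero-centered priors on beta2..beta5 resolve the ridge, and all group-level
statements use the identified composite

    beta_irrelevance = (|beta2 − beta3| + |beta4 − beta5|) / 2,

the mean (not sum) of the two within-feature absolute differences —
a fixed convention; a sum would only rescale group contrasts.

zeta is treated as a *variance* throughout (Gaussian noise on the log-RT
scale). The reporting layer can rescale if an SD convention is preferred.

## Fitting and model evidence

Parameters are estimated per subject by MAP in an unconstrained estimation
space (identity for omega and the betas, log for sigma2_0 and zeta) with
independent Gaussian priors in that space. Defaults: omega ~ N(−3, 16),
log sigma2_0 ~ N(ln 0.05, 1), beta0 ~ N(6, 4), beta1..beta6 ~ N(0, 1),
log zeta ~ N(ln 0.01, 4) — weakly informative around the magnitudes typical
for log-millisecond reaction times. A prior variance of zero pins a
parameter (used heavily by the test oracles). Learning always runs over all
trials — the stimulus stream is observed whether or not the subject
responds — while the likelihood sums over valid trials only (responded,
150–1500 ms).

Optimization is quasi-Newton (L-BFGS-B) from the prior mean plus seeded
perturbed restarts (default 5 starts, 1 prior SD perturbations). Because
the log-joint is exactly quadratic in beta0..beta6 once (omega, sigma2_0,
zeta) are fixed, the optimizer works on the three-dimensional profile
objective with the betas solved in closed form by ridge regression against
their priors at every step. This changes only the route to the optimum,
not the optimum, and is roughly an order of magnitude faster; the identity
is exercised by the conjugate-model tests. The approximate log model
evidence is the Laplace negative free energy at the MAP,
log p(y, theta) + (d/2) ln 2pi − (1/2) ln det H, with H the numerically
differentiated Hessian of the negative log-joint (eigenvalues floored at
1e−6 with a warning flag). For the linear-Gaussian special case this is
exact, which the tests verify against the closed-form marginal likelihood
to 1e−6.

## Model selection

Group-level comparison treats model identity as a random effect: Dirichlet
prior over model frequencies (alpha0 = 1 per model), variational
fixed-point iteration for the posterior concentrations, posterior model
probabilities as expected frequencies, Monte-Carlo exceedance
probabilities (default 1e6 seeded Dirichlet samples), and the Bayesian
omnibus risk from the free-energy comparison of the equal-frequency null
against the fitted alternative. Protected exceedance probabilities shrink
XP toward 1/K by the omnibus risk. Family analyses (learning with/without
precision feedback; 2- vs 3-level; the four response models) re-divide the
prior mass so families are equal a priori and sum sampled frequencies
within families; for K = 2 the exceedance probability is also available in
closed form (regularized incomplete beta) as a test oracle.

## Raw-data analyses

Three paradigm-defined statistics are computed natively on preprocessed
behavior (valid = responded and 150 ms ≤ rt ≤ 1500 ms; natural-log
transform): (i) mean log RT for expected vs. unexpected events of the
relevant feature; (ii) learning curves — within each block the 16 expected
events are split by outcome and grouped in block order into 4 bins of 2
consecutive trials, averaged across blocks; (iii) the ground-truth aberrant
salience score — per test half, the absolute difference in mean raw RT
(milliseconds, untransformed) between the two manifestations of the
currently irrelevant feature, averaged (not summed) over the two halves.
Group comparisons (Welch's test reported as F on 1 and Satterthwaite
degrees of freedom, one-sample t, Spearman) delegate to scipy; repeated-
measures ANOVA machinery is deliberately not re-implemented — the derived
quantities are the contribution, the omnibus tests are routine.

## Synthetic cohorts and what the validation shows

No subject-level data are deposited, so the credibility checks run on
synthetic cohorts drawn from a population centered on the magnitudes of
the original fitted estimates: omega ~ N(−2, 0.3²), beta0 ~ N(6.25, 0.15²),
beta1 ~ N(0.2, 0.1²), beta2..beta5 ~ N(0.03, 0.02²) truncated at 0,
beta6 ~ N(0.07, 0.05²), zeta = 0.04, sigma2_0 held at 0.05 (still estimated
when fitting). Each synthetic subject gets its own seeded trial order.
The generator emulates the design exactly but not everything about real
data: no within-subject drifts, no fatigue or post-error slowing, no
missed responses by default, and Gaussian log-RT noise rather than the
heavier-tailed residuals of real RTs — so passing checks demonstrate the
internal consistency of the pipeline, not field validity on real subjects.

Validation routines default to 2 optimizer starts (the full multistart is
kept for single-subject fits); all runs are seeded end to end.

Two properties of the study conditions deserve emphasis, because the
validation suite measures them honestly:

- **Weak identifiability at the study's noise level.** With noise variance
  0.04 (sd 0.2 log units) the profile likelihood over omega is nearly flat
  across several units, and the sampling error of the within-feature
  coefficient contrasts exceeds the population spread of the generating
  biases. Recovery is therefore excellent for beta0 and beta6, moderate
  for beta1, and poor for omega and beta_irrelevance — an information
  limit of the conditions, not an optimizer failure: as zeta → 0 recovery
  of every identified parameter is exact.
- **Near-equivalence of the model space.** The 16 models differ by well
  under one nat of evidence per subject at this noise level, so
  group-level selection on 20-subject cohorts is dominated by the
  omnibus-risk protection (PXP near uniform) and the top model is
  effectively arbitrary. At low noise the generating response model is
  selected decisively, which is how the selection machinery is validated.

## Numerical conventions

Natural logarithms everywhere. Trial indices are 1-based in all files.
Seeds derive from a single master seed via `numpy.random.default_rng`;
identical seeds give bit-identical results. Convergence: gradient norm
tolerance 1e−5 in estimation space; Hessian steps 1e−3 relative;
ridge systems solved by dense LU (7×7). Degenerate inputs (zero valid
trials, non-positive zeta, invalid trajectories) raise or flag rather than
silently continuing.
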