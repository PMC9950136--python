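# Methods

## The model

`poptensor` models trial-structured spike trains from populations of
non-simultaneously recorded neurons performing delayed-match tasks (a
sample motion stimulus, a delay, a test stimulus, and — on match trials —
a touch-bar release). Spike counts in 5-ms bins are Poisson,

    Y_n(t) ~ Poisson(exp(lambda_n(t)) * Delta),

with a per-neuron log rate built from a baseline, a spike-history term, a
low-rank touch-bar response, and a low-rank stimulus term:

    lambda_n(t) = w_n + (H_n^spk * Y_n)(t)
                + sum_q (T_q^tbar * x^tbar)(t) V_{n,q}^tbar
                + sum_s sum_r (x_s^dir . U_r)(T_r^stim * x_s^timing)(t) V_{n,r}^stim.

The stimulus kernels of all N neurons form the CP (PARAFAC) tensor
K(t,s,n) = sum_r T_r(t) U_{s,r} V_{n,r}: temporal profiles T are shared,
stimulus weights U carry direction/category tuning, and neuron loadings V
define the population subspace. Setting the rank to zero removes the
stimulus term; increasing it approaches independent per-cell GLMs (the
"full-rank" reference). Because neurons enter the likelihood
independently (no noise correlations are modeled), single-electrode
recordings pose no difficulty.

Stimulus parameterizations are nested: `none` (sample/test identity only,
S=2), `category` (S=4), `cosine` (category plus shared cos/sin direction
weights, S=6), `full` (one-hot direction plus test-category kernels,
S=D+2), and independent-sample/test variants. In the `full` model the
per-direction kernels absorb the sample-category response, so the
test-category kernels encode test-minus-sample-category differences; this
keeps the parameterization identifiable. For `full_independent`,
per-direction test kernels already absorb the test category, so that
variant has exactly 2D kernels and no separate category kernels.

An optional *dynamic spike history* extension adds low-rank tensors whose
components multiply a shared filtered-spike-history trace by a gain
kernel locked to stimulus onsets (and optionally the touch-bar release),
so the effective post-spike filter can differ between stimulus-driven and
delay periods while remaining linear in past spiking at every moment.

## Temporal bases

Kernels are expansions in log-stretched raised-cosine bases,
b_j(t) = (1 + cos(pi clip((phi(t)-phi_j)/delta, -1, 1)))/2 with
phi(t) = log(t + stretch * t_peak_last), orthonormalized by QR in peak
order (signs fixed so each column peaks positive). Defaults:

* stimulus — 24 causal functions, stretch 0.2, peaks 40–1540 ms after
  onset, identically zero in the onset bin;
* touch-bar — the first 8 stimulus functions time-reversed, peaks within
  −235…+25 ms around the release (finest resolution near the release);
* spike history — two Kronecker deltas for the first two post-spike bins
  (0–5, 5–10 ms) plus 8 raised cosines with stretch 0.05 and peaks from
  10 to 200 ms. The upper peak is a package choice: with 5-ms bins an
  upper peak anywhere inside the first few bins would collapse all eight
  cosine bumps onto two or three grid points and the basis could not be
  orthonormalized; 200 ms matches the timescales over which post-spike
  effects in these data remain visible. The range is configurable.

Bumps are bin-averaged on a 25-point subgrid so that bumps narrower than
a bin keep their mass.

## Priors and hyperpriors

Stimulus coefficients get zero-mean Gaussian priors assembled from latent
sums: a shared latent (psi_0) correlates all kernels, category latents
(psi_c or psi_s) tie same-category kernels, cos/sin latents (psi_d)
encode smooth cosine tuning, and the per-direction models add a circular
GP over angle, K(th,th') = (1 + (tau+4)/pi d)(1 - d/pi)^(tau+4) with
d = arccos(cos(th-th')), whose arc-length parameter tau >= 0 acts like a
length scale. Spike-history and touch-bar coefficients get i.i.d. normal
priors with scales psi_spk and psi_tbar; baselines are flat. In the
population model the same construction prices the columns of U while T
and V entries are standard normal. Every scale hyperparameter carries a
half-t hyperprior with nu = 4, p(h) ∝ (1 + h²/nu)^(-(nu+1)/2) — finite
and maximal at h = 0, heavy-tailed enough not to fight the data.

## Inference

*Single cells.* MAP by damped Newton iterations (the log posterior is
concave); hyperparameters by maximizing the Laplace approximation of the
evidence times the hyperprior, optimized over log-scales (tau through a
softplus) with Nelder–Mead and warm-started inner fits. The Laplace
correction is exact for conjugate Gaussian problems, which the test suite
verifies against the closed-form marginal likelihood.

*Population model, maximum likelihood* (used for rank selection): L-BFGS
on the packed factors with analytic gradients, random restarts (CP
surfaces are multimodal), and a small ridge (1e-3) on non-baseline
parameters. The ridge exists because Poisson ML diverges along kernel
directions whose support touches only zero-count bins; it is negligible
elsewhere. Initialization follows the generative defaults: standard
normal loadings and history coefficients, random orthonormal temporal
factors, baselines centered on each neuron's empirical log mean rate.

*Population model, Bayesian*: Hamiltonian Monte Carlo over all parameters
and log-transformed hyperparameters. Leapfrog with S = min(100,
ceil(1/eps)) steps; dual averaging (gamma=0.05, t0=10, kappa=0.75)
adapts eps toward 80% acceptance for the first 96% of warmup; the
diagonal mass matrix is re-estimated twice during warmup from inverse
empirical variances (windows at 8–16% and 16–76% of warmup, mirroring
the reference schedule of 25,000 warmup draws at desk scale).
Trajectories with energy error above 1000 (or runaway states) count as
divergences and are rejected. Between HMC steps, each CP component gets
10 Metropolis–Hastings rescaling moves: lognormal(0, 0.2²) factors scale
two factor norms and shrink the third to keep the product fixed, leaving
the likelihood untouched; the acceptance uses the chi-distributed norm
priors with the 1/(u t) change-of-variables factor and the multiplicative
random-walk Hastings correction (one factor of s per scaled leg — the
correction that satisfies detailed balance for that conditional, verified
in the tests against a rejection-sampling oracle).

Model comparison across folds uses the mean held-out log probability per
trial per cell, reported relative to the rank-0 model and normalized by
the per-cell GLM ("fraction of explainable likelihood"); the selected
rank is the smallest whose fraction exceeds 0.9. For posterior-based
comparison, PSIS-LOO (via `arviz.psislw`) gives per-trial elpd values
averaged within neurons, with Pareto-k diagnostics.

## Subspace geometry

The fitted tensor is summarized two ways. (1) HOSVD: the kernel tensor
over sample directions is projected onto its top three neural dimensions
(scaled by 1/sqrt(N)); optionally the across-direction mean is removed
first so shared transients do not dominate. (2) For the cosine model,
direction tuning at each time traces the ellipse E_t(th) = f1(t) cos th +
f2(t) sin th in the orthonormalized output space R = orth(V)' V /
sqrt(N); the major-axis angle is computed in closed form, theta_max =
(1/2) atan2(2 f1.f2, |f1|² − |f2|²), cross-checked at runtime against a
1° grid, and folded into [45°, 225°) because it is only identified modulo
180°. The category vector F_t uses the cs1−cs2 contrast. Applying these
maps per posterior draw yields medians with central 99% credible
intervals. All metrics are invariant to component rescaling and to
orthogonal rotations of the population, which the tests verify.

Near-circular ellipses make theta_max ill-defined; ties are resolved to
the lower angle and flagged degenerate.

## Synthetic populations

The generator emulates the six-direction categorization task: directions
every 60° from 15°, a 45°–225° category boundary, 650-ms stimuli, a
1000-ms delay, and a uniform 200–500 ms reaction time before the
touch-bar release on match trials (the modeled window ends 50 ms after
the release, or 50 ms after test offset otherwise). Defaults: baseline
20 sp/s (lognormal across cells, sd 0.3) and a peak log-rate modulation
of 1.2 — roughly threefold rate swings, typical of well-tuned parietal
cells. Components are balanced to equal kernel-tensor contributions so
every generative dimension is comparably strong. Templates control the
stimulus weights: `categoryless` (no stimulus signal), `category_axis`,
`circular_direction` (an exactly circular direction representation: two
equal-norm components with orthogonal cos/sin weights sharing one
temporal kernel), and `mixed`. Spiking is simulated bin by bin so history
feedback sees the realized spikes; the per-bin log expected count is
clipped at +4 for safety and clips are counted.

What the generator does **not** emulate: noise correlations between
neurons, non-Poisson variability beyond history effects, error trials and
behavioral lapses, eye-movement or attention covariates, and slow
nonstationarities across sessions. Passing recovery tests therefore show
the estimators work when the model class contains the truth, not that
cortical data satisfy these assumptions.

## Desk-scale study conditions

Heavy checks run on a compact variant of the task chosen once: 200-ms
stimuli, 200-ms delay, no touch-bar, and a stimulus basis of 8 functions
with peaks 40–200 ms so that every kernel lag is observable inside the
modeled window (at full scale the window truncates the test-stimulus
kernels; unobservable coefficients would make maximum likelihood
ill-posed). Under these conditions:

* parameter recovery uses rank-2 truths, N = 20 neurons, 100 trials per
  direction, and 3 optimizer restarts;
* rank selection uses 2-fold cross-validation over ranks 0–3 with a
  stimulus-only per-cell reference fit at saturated rank (min(P, S) per
  cell, exactly the per-cell GLM stimulus model) whose ridge strength is
  chosen per neuron by inner validation — the cheap analog of per-cell
  evidence optimization. The package default for real analyses remains
  10-fold.
* the HMC acceptance study samples a rank-1, N = 5 population (20 trials
  per direction) with 2,500 warmup and 2,500 retained draws;
* decoder calibration uses direction-independent populations of N = 20
  cells, 100 simulated trials per direction, 200-ms count windows, and
  pseudopopulations of 50 trials per direction. At this size the
  dataset-level bias of the generalization decoder (from resampling a
  fixed set of empirical condition means) stays within about one
  percentage point of chance.

## Numerical choices

* Bins are half-open [t, t+Delta); spikes at the window end are excluded.
* Fold assignment shuffles within (neuron, sample-direction) strata with
  a seeded generator before round-robin dealing; per-stratum fold sizes
  differ by at most one.
* The log expected count is capped at 30 inside optimization objectives
  (an overflow guard that never binds near an optimum).
* Trials sharing event times are grouped; when the model has no history
  term, trials identical in (neuron, events, direction coefficients,
  length) collapse into summed counts with a multiplicity weight — both
  the likelihood and its gradient are linear in the per-bin residual, so
  the collapse is exact.
* Cross-validated model comparisons evaluate the full Poisson pmf
  (including log y! terms), so values are comparable across models.
* Logistic decoders: z-scoring fit on training data only (variances
  floored at 1e-12), L2 penalty 0.1 on half the squared weight norm in
  the summed-loss objective (scikit-learn C = 10), solver tolerance 1e-8.

## Known limitations

* The MH rescaling move assumes Gaussian (or chi-norm) priors on the
  factor legs; it is skipped for zero-norm components.
* Laplace evidence optimization refits the MAP at every hyperparameter
  evaluation; for large single-cell designs this is the slowest path in
  the package.
* `full_independent` shares the stimulus-independent latent between
  sample and test roles; other cross-role correlation structures are not
  implemented.
* PSIS-LOO requires storing per-trial log-likelihood draws; for long
  chains use thinning.
* The closed-form ellipse axis assumes the cosine parameterization; for
  `full` models, geometry should be read from the HOSVD trajectories.
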