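# poptensor

Low-rank tensor point-process models for neural population spike trains
recorded in delayed-match tasks.

## The problem

In delayed-match-to-category experiments, a monkey sees a sample motion
stimulus, holds it across a delay, and compares it to a test stimulus,
releasing a touch bar on a match; motion directions split into two
categories along a fixed 45°–225° boundary. Parietal neurons recorded one
at a time during such tasks show mixed, time-varying selectivity for
direction, category, task epoch, and the animal's report. Trial-averaged
dimensionality reduction struggles here: trials end at variable times,
direction and category are perfectly confounded in the stimulus set, and
spike trains are not Gaussian.

`poptensor` takes an encoding-model route. Every neuron n gets a Poisson
point-process GLM for its binned spike counts,

    Y_n(t) ~ Poisson(exp(λ_n(t)) Δ),
    λ_n(t) = w_n + (H^spk_n ∗ Y_n)(t) + Σ_q (T^tbar_q ∗ x^tbar)(t) V^tbar_{n,q}
             + Σ_s Σ_r (x^dir_s · U_r) (T^stim_r ∗ x^timing_s)(t) V^stim_{n,r},

and the population's stimulus kernels are tied together through a rank-R
CP (PARAFAC) tensor K(t,s,n) = Σ_r T_r(t) U_{s,r} V_{n,r}. Shared
temporal factors T, stimulus weights U and neuron loadings V give a
low-dimensional, single-trial account of how direction and category are
encoded — one that handles unequal trial lengths, spike-history effects
and non-simultaneous recordings natively. The package provides:

* nested stimulus parameterizations (timing-only → category → cosine
  direction tuning → per-direction kernels) with structured Gaussian
  priors, including a circular Gaussian process over direction;
* single-cell GLM fitting (MAP with Laplace-evidence hyperparameter
  optimization) as the full-rank reference;
* maximum-likelihood tensor fitting, cross-validated rank selection, and
  Hamiltonian Monte Carlo over parameters and log-hyperparameters with a
  component-rescaling Metropolis step and PSIS-LOO model comparison;
* dynamic spike-history extensions (post-spike filters whose gain is
  locked to task events);
* subspace geometry: HOSVD trajectories, the direction-tuning ellipse,
  category-vector norms, with posterior credible intervals;
* pseudopopulation decoding (direction-split category generalization,
  match/non-match cross-decoding) and classical single-neuron indices
  (rCTI, rDSI, parametric tuning curves, beta-binomial behavior);
* a ground-truth simulator for all of the above.

## Worked example

```python
import numpy as np
from poptensor import GmlmModel, TaskSchedule, sample_ground_truth, simulate_trials
from poptensor.synthetic import recovery_report

# simulate a 12-neuron population with mixed direction + category tuning
sched = TaskSchedule().compact()          # short trials for a quick demo
truth = sample_ground_truth("mixed", N=12, rank=2, seed=1, schedule=sched)
data = simulate_trials(truth, trials_per_direction=50, seed=2)

# fit the rank-2 tensor model by maximum likelihood
model = GmlmModel(truth.model.spec, truth.model.bases, n_neurons=12, rank=2,
                  include_history=False, include_tbar=False,
                  bin_width=data.bin_width)
design = model.build_design(data)
params = model.fit_mle(design, rng=np.random.default_rng(0), n_restarts=3)

rep = recovery_report(truth, params)
print(f"log-likelihood  {model.log_likelihood(params, design):.1f}")
print(f"kernel rel. err {rep['kernel_rel_error']:.3f}")
print("principal angles", np.round(rep["principal_angles_deg"], 1))
```

Output:

```
log-likelihood  -162568.9
kernel rel. err 0.279
principal angles [11.2  6.1]
```

The log-likelihood is the Poisson log probability of all 3,600 trials
under the fit. The kernel relative error compares the fitted stimulus
kernel tensor against the generative one (28% at this modest trial
count; it drops below 15% at 100 trials per direction), and the
principal angles show that the fitted two-dimensional neuron-loading
subspace lies within about ten degrees of the true encoding subspace.

From a shell, the same workflow is available as
`poptensor simulate | fit-gmlm | rank-select | sample | decode |
single-neuron`.

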