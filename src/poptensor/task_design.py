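"""Stimulus parameterizations and per-trial regressors.

The delayed-match tasks are linearized as point events: a unit impulse at
sample onset, a unit impulse at test onset and (on release trials) a unit
impulse at the touch-bar release. What distinguishes the nested model
family is the coefficient vector attached to each stimulus impulse:

  ``none``                sample/test identity only                (S = 2)
  ``category``            identity x category                     (S = 4)
  ``cosine``              category + shared cos/sin direction      (S = 6)
  ``full``                one-hot direction + test-category        (S = D + 2)
  ``cosine_independent``  category + per-role cos/sin              (S = 8)
  ``full_independent``    per-role one-hot direction               (S = 2D)

In the ``full`` model the per-direction kernels absorb the sample-category
response (identifiability), so the test-category kernels encode the test
response minus the same-category sample response. In ``full_independent``
the sample and test directions get separate one-hot blocks; per-direction
test kernels already absorb the test category, so no extra category
kernels are added.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_data import CATEGORY_BOUNDARY_DEG, Trial, category_of

PARAMETERIZATIONS = (
    "none",
    "category",
    "cosine",
    "full",
    "cosine_independent",
    "full_independent",
)


@dataclass(frozen=True)
class DesignSpec:
    """One stimulus parameterization over a fixed direction set."""

    parameterization: str = "cosine"
    direction_set_deg: tuple[float, ...] = (15.0, 75.0, 135.0, 195.0, 255.0, 315.0)
    boundary_deg: tuple[float, float] = CATEGORY_BOUNDARY_DEG

    def __post_init__(self):
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")

    @property
    def D(self) -> int:
        return len(self.direction_set_deg)

    @property
    def S(self) -> int:
        p = self.parameterization
        return {
            "none": 2,
            "category": 4,
            "cosine": 6,
            "full": self.D + 2,
            "cosine_independent": 8,
            "full_independent": 2 * self.D,
        }[p]

    @property
    def shared_direction_tuning(self) -> bool:
        return self.parameterization in ("none", "category", "cosine", "full")

    def coefficient_labels(self) -> list[str]:
        p = self.parameterization
        dirs = [f"theta_{d:g}" for d in self.direction_set_deg]
        if p == "none":
            return ["sample", "test"]
        if p == "category":
            return ["cs1", "cs2", "ct1", "ct2"]
        if p == "cosine":
            return ["cs1", "cs2", "ct1", "ct2", "cos", "sin"]
        if p == "full":
            return ["ct1", "ct2"] + dirs
        if p == "cosine_independent":
            return ["cs1", "cs2", "ct1", "ct2", "cos_s", "sin_s", "cos_t", "sin_t"]
        return [f"s_{lab}" for lab in dirs] + [f"t_{lab}" for lab in dirs]

    def index(self, label: str) -> int:
        return self.coefficient_labels().index(label)

    def category(self, theta_deg: float) -> int:
        return category_of(theta_deg, self.boundary_deg)


@dataclass
class TrialRegressors:
    """Numeric regressors for one trial under a DesignSpec."""

    x_timing_sample: np.ndarray  # per-bin unit impulse at sample onset
    x_timing_test: np.ndarray
    x_tbar: np.ndarray  # per-bin impulse at release; all-zero if none
    x_dir_sample: np.ndarray  # length-S coefficient vector
    x_dir_test: np.ndarray


def build_timing(trial: Trial) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-impulse timing regressors for sample, test and touch-bar events."""
    T = trial.n_bins
    for ev in (trial.t_sample_on, trial.t_test_on):
        if not (0 <= ev < T):
            raise ValueError("event bin outside trial window")
    xs = np.zeros(T)
    xt = np.zeros(T)
    xb = np.zeros(T)
    xs[trial.t_sample_on] = 1.0
    xt[trial.t_test_on] = 1.0
    if trial.t_tbar is not None:
        xb[trial.t_tbar] = 1.0
    return xs, xt, xb


def stimulus_coefficients(
    theta_deg: float, category: int, role: str, spec: DesignSpec
) -> np.ndarray:
    """Length-S coefficient vector for one stimulus event.

    ``role`` is ``"sample"`` or ``"test"``; ``category`` in {1, 2}.
    """
    if role not in ("sample", "test"):
        raise ValueError("role must be 'sample' or 'test'")
    p = spec.parameterization
    x = np.zeros(spec.S)
    rad = np.deg2rad(theta_deg)
    if p == "none":
        x[spec.index(role)] = 1.0
    elif p == "category":
        x[spec.index(f"c{'s' if role == 'sample' else 't'}{category}")] = 1.0
    elif p == "cosine":
        x[spec.index(f"c{'s' if role == 'sample' else 't'}{category}")] = 1.0
        x[spec.index("cos")] = np.cos(rad)
        x[spec.index("sin")] = np.sin(rad)
    elif p == "cosine_independent":
        suffix = "s" if role == "sample" else "t"
        x[spec.index(f"c{suffix}{category}")] = 1.0
        x[spec.index(f"cos_{suffix}")] = np.cos(rad)
        x[spec.index(f"sin_{suffix}")] = np.sin(rad)
    elif p == "full":
        lab = f"theta_{theta_deg:g}"
        if lab not in spec.coefficient_labels():
            raise ValueError(f"direction {theta_deg} not in the design's direction set")
        x[spec.index(lab)] = 1.0
        if role == "test":
            x[spec.index(f"ct{category}")] = 1.0
    else:  # full_independent
        lab = f"{'s' if role == 'sample' else 't'}_theta_{theta_deg:g}"
        if lab not in spec.coefficient_labels():
            raise ValueError(f"direction {theta_deg} not in the design's direction set")
        x[spec.index(lab)] = 1.0
    return x


def trial_regressors(trial: Trial, spec: DesignSpec) -> TrialRegressors:
    xs, xt, xb = build_timing(trial)
    return TrialRegressors(
        x_timing_sample=xs,
        x_timing_test=xt,
        x_tbar=xb,
        x_dir_sample=stimulus_coefficients(trial.theta_sample, trial.c_sample, "sample", spec),
        x_dir_test=stimulus_coefficients(trial.theta_test, trial.c_test, "test", spec),
    )


def glm_kernel_set(spec: DesignSpec) -> list[str]:
    """Labels of the stimulus kernels of the GLM with the same parameterization."""
    return spec.coefficient_labels()


def modelable(trial: Trial, spec: DesignSpec) -> bool:
    """Trials used for fitting: correct, off-boundary, directions in the set."""
    if not trial.correct:
        return False
    try:
        spec.category(trial.theta_sample)
        spec.category(trial.theta_test)
    except ValueError:
        return False
    if spec.parameterization in ("full", "full_independent"):
        if trial.theta_sample not in spec.direction_set_deg:
            return False
        if trial.theta_test not in spec.direction_set_deg:
            return False
    return True


def nesting_map(coarse: DesignSpec, fine: DesignSpec) -> np.ndarray:
    """Matrix A with x_coarse = A @ x_fine for every stimulus event.

    Witnesses the nesting of the parameterizations: the ``none`` design is
    a linear function of ``category``, which is linear in ``cosine``, which
    is linear in ``full``. Built column-by-column by evaluating both designs
    on every (direction, role) combination and solving the linear system.
    """
    rows_f, rows_c = [], []
    for role in ("sample", "test"):
        for theta in fine.direction_set_deg:
            c = fine.category(theta)
            rows_f.append(stimulus_coefficients(theta, c, role, fine))
            rows_c.append(stimulus_coefficients(theta, c, role, coarse))
    Xf = np.array(rows_f)
    Xc = np.array(rows_c)
    A, res, rank, _ = np.linalg.lstsq(Xf, Xc, rcond=None)
    resid = Xf @ A - Xc
    if np.max(np.abs(resid)) > 1e-8:
        raise ValueError("designs are not nested")
    return A.T
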