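"""Synthetic cohort generation for attrition studies.

The generative model is a baseline-complete cohort of size ``n`` in which a
continuous outcome may be missing at follow-up through total non-response
(attrition).  Seven covariates ``z1..z7`` are independent standard normals;
a continuous exposure ``x`` loads on ``z1, z2, z5, z6``; a continuous
outcome ``y`` loads on the exposure and on ``z1, z3, z5, z7``; and the
probability of responding at follow-up follows a logistic model on the
outcome, the exposure and ``z1..z4``:

    x = 1 + a1*z1 + a2*z2 + a5*z5 + a6*z6 + eps,        eps  ~ N(0, 1)
    y = 1 + b*x + b1*z1 + b3*z3 + b5*z5 + b7*z7 + eps',  eps' ~ N(0, 1)
    logit(p) = g0 + gy*y + gx*x + g1*z1 + g2*z2 + g3*z3 + g4*z4

``z1`` and ``z5`` are confounders (associated with both exposure and
outcome), ``z3`` and ``z7`` are prognostic only, ``z2`` and ``z6`` are
exposure-only, and ``z4`` predicts response only.  The pair ``(gx, gy)``
indexes the attrition mechanism: ``gy = 0`` is missing-at-random (MAR,
response independent of the unobserved outcome given observed data), and
``gy > 0`` is missing-not-at-random (MNAR).

The response intercept ``g0`` is calibrated per scenario so that the
population mean response probability equals a target rate (default 60%).
Because ``(x, y, z)`` are jointly Gaussian, the linear predictor of the
response model is exactly Gaussian, so the calibration is done by
deterministic Gauss-Hermite quadrature plus bracketed root-finding rather
than by simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "N_COVARIATES",
    "GenerativeParams",
    "ScenarioSpec",
    "CohortSample",
    "SCENARIO_GRID",
    "default_scenarios",
    "get_scenario",
    "generate_covariates",
    "generate_exposure",
    "generate_outcome",
    "response_probabilities",
    "linear_predictor_moments",
    "calibrate_gamma0",
    "draw_response",
    "generate_cohort",
]

N_COVARIATES = 7

# 0-based covariate indices entering each sub-model.
_EXPOSURE_COVS = (0, 1, 4, 5)   # z1, z2, z5, z6
_OUTCOME_COVS = (0, 2, 4, 6)    # z1, z3, z5, z7
_RESPONSE_COVS = (0, 1, 2, 3)   # z1, z2, z3, z4


@dataclass(frozen=True)
class GenerativeParams:
    """Coefficients of the generative model with the study defaults.

    ``alpha`` are the exposure loadings on (z1, z2, z5, z6); ``beta_true``
    is the true exposure effect; ``beta_cov`` are the outcome loadings on
    (z1, z3, z5, z7); ``gamma_cov`` are the response loadings on
    (z1, z2, z3, z4).  ``noise_free`` forces eps = eps' = 0 and exists for
    testing exact algebraic identities only.
    """

    n: int = 1000
    alpha: tuple[float, float, float, float] = (0.218, 0.218, 0.218, 0.218)
    beta_true: float = 0.5
    beta_cov: tuple[float, float, float, float] = (0.170, 0.230, 0.170, 0.230)
    gamma_cov: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.1)
    target_response_rate: float = 0.60
    noise_free: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        if not 0.0 < self.target_response_rate < 1.0:
            raise ValueError(
                "target_response_rate must lie strictly in (0, 1), got "
                f"{self.target_response_rate}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """One attrition mechanism: response loadings on exposure and outcome.

    ``gamma_0`` is the calibrated intercept; it is ``None`` until
    :func:`calibrate_gamma0` has been applied (see :meth:`calibrate`).
    """

    name: str
    gamma_x: float
    gamma_y: float
    gamma_0: float | None = None

    @property
    def mechanism_class(self) -> str:
        return "MAR" if self.gamma_y == 0.0 else "MNAR"

    @property
    def is_calibrated(self) -> bool:
        return self.gamma_0 is not None

    def calibrate(self, params: GenerativeParams | None = None) -> "ScenarioSpec":
        """Return a copy with ``gamma_0`` set to hit the target response rate."""
        params = params or GenerativeParams()
        g0 = calibrate_gamma0(self, params)
        return dataclasses.replace(self, gamma_0=g0)


#: The nine-scenario grid: gamma_x in {0, .2, .5} crossed with gamma_y in
#: {0, .2, .5}; MAR rows have gamma_y = 0, MNAR rows gamma_y > 0.
SCENARIO_GRID: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("MAR 1", 0.0, 0.0),
    ScenarioSpec("MAR 2", 0.2, 0.0),
    ScenarioSpec("MAR 3", 0.5, 0.0),
    ScenarioSpec("MNAR 1", 0.0, 0.2),
    ScenarioSpec("MNAR 2", 0.2, 0.2),
    ScenarioSpec("MNAR 3", 0.5, 0.2),
    ScenarioSpec("MNAR 4", 0.0, 0.5),
    ScenarioSpec("MNAR 5", 0.2, 0.5),
    ScenarioSpec("MNAR 6", 0.5, 0.5),
)


def default_scenarios(params: GenerativeParams | None = None) -> list[ScenarioSpec]:
    """The built-in nine scenarios, each with its intercept calibrated."""
    params = params or GenerativeParams()
    return [s.calibrate(params) for s in SCENARIO_GRID]


def get_scenario(name: str, params: GenerativeParams | None = None) -> ScenarioSpec:
    """Look up a grid scenario by name (e.g. ``"MNAR 6"``), calibrated."""
    for s in SCENARIO_GRID:
        if s.name == name:
            return s.calibrate(params)
    known = ", ".join(s.name for s in SCENARIO_GRID)
    raise KeyError(f"unknown scenario {name!r}; known scenarios: {known}")


@dataclass
class CohortSample:
    """One simulated cohort.

    ``y`` holds the full outcome vector (the simulation truth); analysts
    must access outcomes only through :attr:`y_observed`, which blanks the
    outcome of non-respondents.
    """

    z: np.ndarray          # n x 7 covariate matrix
    x: np.ndarray          # exposure
    y: np.ndarray          # outcome (truth, includes non-respondents)
    p: np.ndarray          # true response probabilities
    r: np.ndarray          # response indicator in {0, 1}
    scenario: ScenarioSpec
    seed_used: object = None

    @property
    def n(self) -> int:
        return self.z.shape[0]

    @property
    def respondent_mask(self) -> np.ndarray:
        return self.r.astype(bool)

    @property
    def y_observed(self) -> np.ndarray:
        """Outcome with non-respondents masked to NaN (the observed view)."""
        out = self.y.copy()
        out[~self.respondent_mask] = np.nan
        return out

    @property
    def response_rate(self) -> float:
        return float(self.r.mean())

    def column(self, name: str) -> np.ndarray:
        """Fetch a named analysis column: 'x', 'z1'..'z7' ('y' is refused)."""
        if name == "x":
            return self.x
        if name.startswith("z"):
            k = int(name[1:])
            if not 1 <= k <= N_COVARIATES:
                raise KeyError(name)
            return self.z[:, k - 1]
        if name == "y":
            raise KeyError(
                "the outcome is not addressable as a design column: it is "
                "unobserved for non-respondents (use y_observed explicitly)"
            )
        raise KeyError(name)

    def to_frame(self, observed: bool = True):
        """As a DataFrame with columns z1..z7, x, y, p, r.

        With ``observed=True`` the outcome column is the observed view
        (NaN for non-respondents, written as empty cells in CSV).
        """
        import pandas as pd

        data = {f"z{k + 1}": self.z[:, k] for k in range(N_COVARIATES)}
        data["x"] = self.x
        data["y"] = self.y_observed if observed else self.y
        data["p"] = self.p
        data["r"] = self.r
        return pd.DataFrame(data)

    def to_csv(self, path, observed: bool = True) -> None:
        self.to_frame(observed=observed).to_csv(path, index=False)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_covariates(n: int, rng) -> np.ndarray:
    """Draw the n x 7 matrix of independent standard-normal covariates."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return _as_rng(rng).standard_normal((n, N_COVARIATES))


def generate_exposure(
    z: np.ndarray, params: GenerativeParams, rng
) -> np.ndarray:
    """Exposure: x = 1 + a1*z1 + a2*z2 + a5*z5 + a6*z6 + eps."""
    z = np.asarray(z)
    if z.ndim != 2 or z.shape[1] != N_COVARIATES:
        raise ValueError(f"z must have {N_COVARIATES} columns, got shape {z.shape}")
    x = 1.0 + z[:, _EXPOSURE_COVS] @ np.asarray(params.alpha)
    if not params.noise_free:
        x = x + _as_rng(rng).standard_normal(z.shape[0])
    return x


def generate_outcome(
    x: np.ndarray, z: np.ndarray, params: GenerativeParams, rng
) -> np.ndarray:
    """Outcome: y = 1 + b*x + b1*z1 + b3*z3 + b5*z5 + b7*z7 + eps'."""
    x = np.asarray(x)
    z = np.asarray(z)
    if z.ndim != 2 or z.shape[1] != N_COVARIATES or x.shape[0] != z.shape[0]:
        raise ValueError(
            f"x and z are not conformable: x has shape {x.shape}, z {z.shape}"
        )
    y = 1.0 + params.beta_true * x + z[:, _OUTCOME_COVS] @ np.asarray(params.beta_cov)
    if not params.noise_free:
        y = y + _as_rng(rng).standard_normal(z.shape[0])
    return y


def response_probabilities(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    scenario: ScenarioSpec,
    params: GenerativeParams,
) -> np.ndarray:
    """Per-individual response probabilities under the logistic model."""
    if scenario.gamma_0 is None:
        raise RuntimeError(
            f"scenario {scenario.name!r} has no calibrated intercept; call "
            "ScenarioSpec.calibrate() first"
        )
    eta = (
        scenario.gamma_0
        + scenario.gamma_y * np.asarray(y)
        + scenario.gamma_x * np.asarray(x)
        + np.asarray(z)[:, _RESPONSE_COVS] @ np.asarray(params.gamma_cov)
    )
    return expit(eta)


def linear_predictor_moments(
    scenario: ScenarioSpec, params: GenerativeParams
) -> tuple[float, float]:
    """Mean and SD of the response linear predictor, excluding the intercept.

    Writes eta = gy*y + gx*x + sum_k g_k*z_k as a linear combination of the
    nine independent standard normals (z1..z7, eps, eps'); the mean and
    variance follow in closed form.
    """
    b = params.beta_true
    # Coefficient of x and y on each latent normal (z1..z7, eps, eps').
    x_load = np.zeros(N_COVARIATES + 2)
    x_load[list(_EXPOSURE_COVS)] = params.alpha
    x_load[N_COVARIATES] = 1.0            # eps
    y_load = b * x_load
    y_load[list(_OUTCOME_COVS)] += params.beta_cov
    y_load[N_COVARIATES + 1] = 1.0        # eps'
    if params.noise_free:
        x_load[N_COVARIATES:] = 0.0
        y_load[N_COVARIATES:] = 0.0

    eta_load = scenario.gamma_y * y_load + scenario.gamma_x * x_load
    eta_load[list(_RESPONSE_COVS)] += params.gamma_cov

    x_mean, y_mean = 1.0, 1.0 + b  # E[x] = 1, E[y] = 1 + b*E[x]
    mu = scenario.gamma_y * y_mean + scenario.gamma_x * x_mean
    sigma = float(np.sqrt(np.sum(eta_load**2)))
    return mu, sigma


_GH_NODES = 64


def calibrate_gamma0(
    scenario: ScenarioSpec,
    params: GenerativeParams,
    target_rate: float | None = None,
    n_nodes: int = _GH_NODES,
) -> float:
    """Solve for the intercept giving the target mean response probability.

    E[expit(g0 + eta)] with Gaussian eta is evaluated by Gauss-Hermite
    quadrature and the root in g0 is found by Brent's method.  The result
    is deterministic (no Monte-Carlo noise) and reproducible.
    """
    target = params.target_response_rate if target_rate is None else target_rate
    if not 0.0 < target < 1.0:
        raise ValueError(f"target rate must lie in (0, 1), got {target}")
    mu, sigma = linear_predictor_moments(scenario, params)
    if sigma == 0.0:
        return float(logit(target) - mu)
    nodes, weights = hermgauss(n_nodes)
    # E[f(mu + sigma*Z)] = (1/sqrt(pi)) * sum_j w_j f(mu + sigma*sqrt(2)*t_j)
    shift = mu + sigma * np.sqrt(2.0) * nodes
    w = weights / np.sqrt(np.pi)

    def mean_rate(g0: float) -> float:
        return float(w @ expit(g0 + shift)) - target

    lo = logit(target) - mu - 10.0 * sigma - 1.0
    hi = logit(target) - mu + 10.0 * sigma + 1.0
    if mean_rate(lo) > 0 or mean_rate(hi) < 0:
        raise RuntimeError(
            f"calibration root not bracketed for scenario {scenario.name!r}"
        )
    return float(brentq(mean_rate, lo, hi, xtol=1e-12, rtol=8.9e-16))


def draw_response(p: np.ndarray, rng) -> np.ndarray:
    """Independent Bernoulli response indicators with probabilities p."""
    p = np.asarray(p)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("response probabilities must lie strictly in (0, 1)")
    return (_as_rng(rng).random(p.shape) < p).astype(np.int8)


def generate_cohort(
    scenario: ScenarioSpec,
    params: GenerativeParams | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> CohortSample:
    """Draw one complete cohort under a calibrated scenario.

    All stochastic pieces (covariates, both noise terms, the response
    draw) come from a single generator, so a fixed ``seed`` reproduces the
    sample byte-for-byte.
    """
    params = params or GenerativeParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    z = generate_covariates(params.n, rng)
    x = generate_exposure(z, params, rng)
    y = generate_outcome(x, z, params, rng)
    p = response_probabilities(x, y, z, scenario, params)
    r = draw_response(p, rng)
    return CohortSample(z=z, x=x, y=y, p=p, r=r, scenario=scenario, seed_used=seed)
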