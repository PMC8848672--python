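"""Estimators: complete-case analysis and inverse-probability-of-participation
weighting (IPPW) for a linear association model with a missing outcome.

The association model of interest is the parsimonious epidemiological
regression of the outcome on the exposure plus the two confounders:

    y = b0 + b*x + c1*z1 + c5*z5 + e

CCA fits it by ordinary least squares among respondents only.  IPPW first
fits a logistic response model (participation indicator regressed on fully
observed baseline variables over the whole cohort), then reweights
respondents by w_i = 1 / p_hat_i and fits the association model by weighted
least squares.  The outcome is never a permitted regressor of the response
model, since it is unobserved for non-respondents.

Standard errors: CCA uses the classical model-based OLS standard error.
IPPW defaults to the heteroscedasticity-robust (HC0) sandwich treating the
weights as fixed; ``se_method="model"`` selects the model-based WLS
standard error instead.  ``se_method`` is a pluggable label so that a
linearization-based estimator accounting for weight estimation can be
registered later.

The logistic solver is a small Newton-Raphson (IRLS) routine written here
because the Monte-Carlo engine performs hundreds of thousands of fits and
per-fit overhead dominates; it is cross-validated against statsmodels in
the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .datagen import CohortSample

__all__ = [
    "EstimationError",
    "DegenerateDesignError",
    "DegenerateResponseError",
    "ConvergenceError",
    "ResponseModelSpec",
    "RESPONSE_MODELS",
    "response_model",
    "default_response_models",
    "EstimateRecord",
    "LogisticFit",
    "fit_logistic",
    "fit_response_model",
    "compute_weights",
    "fit_association_cca",
    "fit_association_ippw",
    "wald_ci",
    "ASSOCIATION_TERMS",
    "parse_formula",
    "fit_cca_frame",
    "fit_ippw_frame",
]


class EstimationError(RuntimeError):
    """Base class for estimation failures."""


class DegenerateDesignError(EstimationError):
    """Design matrix is rank-deficient or has too few respondents."""


class DegenerateResponseError(EstimationError):
    """Everyone responded or nobody did: no response model is estimable."""


class ConvergenceError(EstimationError):
    """Logistic likelihood maximisation failed to converge (e.g. separation)."""


class InvalidProbabilityError(EstimationError, ValueError):
    """Fitted response probabilities reached 0 or 1 (weights undefined)."""


_ALLOWED_VARIABLES = frozenset({"x"} | {f"z{k}" for k in range(1, 8)})

#: Regressors of the association model (intercept is implicit).
ASSOCIATION_TERMS: tuple[str, ...] = ("x", "z1", "z5")


@dataclass(frozen=True)
class ResponseModelSpec:
    """A response-model variable set.

    Built-in models 1..9 include the exposure ``x``; models 10..18 are the
    same sets without it.  ``model_id=0`` marks a free-form (applied-mode)
    set.  The outcome is never admissible.
    """

    model_id: int
    variables: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [v for v in self.variables if v not in _ALLOWED_VARIABLES]
        if bad:
            raise ValueError(
                f"inadmissible response-model variables {bad}; the outcome is "
                "unobserved for non-respondents and cannot enter the response "
                "model; allowed: x, z1..z7"
            )
        if len(set(self.variables)) != len(self.variables):
            raise ValueError(f"duplicate variables in {self.variables}")

    @property
    def includes_exposure(self) -> bool:
        return "x" in self.variables

    @property
    def label(self) -> str:
        return f"IPPW(model {self.model_id})" if self.model_id else "IPPW(custom)"


def _grid() -> dict[int, ResponseModelSpec]:
    with_x = {
        1: ("x", "z1", "z2", "z3", "z4"),
        2: ("x", "z1", "z2", "z3", "z4", "z5", "z6", "z7"),
        3: ("x", "z1", "z3"),
        4: ("x", "z1", "z2", "z3", "z5", "z7"),
        5: ("x", "z1"),
        6: ("x", "z5"),
        7: ("x", "z1", "z5"),
        8: ("x", "z1", "z5", "z7"),
        9: ("x", "z5", "z7"),
    }
    out = {k: ResponseModelSpec(k, v) for k, v in with_x.items()}
    for k, v in with_x.items():
        out[k + 9] = ResponseModelSpec(k + 9, tuple(t for t in v if t != "x"))
    return out


#: The eighteen built-in response models (1..9 with exposure, 10..18 without).
RESPONSE_MODELS: dict[int, ResponseModelSpec] = _grid()


def response_model(model_id: int) -> ResponseModelSpec:
    try:
        return RESPONSE_MODELS[model_id]
    except KeyError:
        raise KeyError(f"response model id must be in 1..18, got {model_id}") from None


def default_response_models() -> list[ResponseModelSpec]:
    return [RESPONSE_MODELS[k] for k in range(1, 19)]


@dataclass(frozen=True)
class EstimateRecord:
    """One fitted association model."""

    estimator_label: str
    beta_hat: float
    se: float
    ci_lower: float
    ci_upper: float
    n_respondents: int
    response_fit_converged: bool = True
    weight_summary: tuple[float, float, float] = (1.0, 1.0, 1.0)


@dataclass
class LogisticFit:
    """Diagnostics of one logistic response fit."""

    coef: np.ndarray
    p_hat: np.ndarray
    converged: bool
    n_iter: int
    variables: tuple[str, ...]


def fit_logistic(
    X: np.ndarray,
    r: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, bool, int]:
    """Newton-Raphson MLE for logistic regression of r on X (with intercept
    as the first column of X).  Returns (coef, converged, n_iter).

    Convergence: max absolute coefficient update < tol (sample-size
    invariant).  Quasi-separation shows up as non-convergence or a singular
    Hessian and is reported, not masked.
    """
    n, k = X.shape
    beta = np.zeros(k)
    rate = r.mean()
    beta[0] = logit(rate)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        score = X.T @ (r - p)
        w = p * (1.0 - p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular Hessian at iteration {it} (separation or collinear "
                "response-model design)"
            ) from exc
        # Step-halving keeps the likelihood ascent stable near separation.
        ll = np.sum(r * eta - np.logaddexp(0.0, eta))
        for _ in range(20):
            cand = beta + step
            eta_c = X @ cand
            ll_c = np.sum(r * eta_c - np.logaddexp(0.0, eta_c))
            if ll_c >= ll - 1e-12:
                break
            step *= 0.5
        beta = cand
        if np.max(np.abs(step)) < tol:
            return beta, True, it
    return beta, False, max_iter


def _design_from_sample(sample: CohortSample, variables: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(sample.n)]
    cols.extend(sample.column(v) for v in variables)
    return np.column_stack(cols)


def fit_response_model(sample: CohortSample, spec: ResponseModelSpec) -> LogisticFit:
    """ML logistic regression of the response indicator on the spec's
    variables, over the full cohort (respondents and non-respondents).

    With the intercept included, the score equations force the mean fitted
    probability to equal the observed response rate exactly.
    """
    r = sample.r.astype(float)
    n_resp = int(r.sum())
    if n_resp == 0 or n_resp == sample.n:
        raise DegenerateResponseError(
            f"{n_resp} of {sample.n} responded: response model is not estimable"
        )
    X = _design_from_sample(sample, spec.variables)
    coef, converged, n_iter = fit_logistic(X, r)
    if not converged:
        raise ConvergenceError(
            f"logistic response fit did not converge in {n_iter} iterations "
            f"(model {spec.model_id}, variables {spec.variables})"
        )
    p_hat = expit(X @ coef)
    return LogisticFit(
        coef=coef, p_hat=p_hat, converged=converged, n_iter=n_iter,
        variables=spec.variables,
    )


def compute_weights(p_hat: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Inverse-probability weights w = 1/p_hat over respondents (r = 1).

    No truncation or normalisation is applied: each respondent carries
    their own weight plus that of the non-respondents they stand in for
    (Horvitz-Thompson: sum of weights estimates the cohort size).
    """
    p_hat = np.asarray(p_hat, dtype=float)
    mask = np.asarray(r).astype(bool)
    p_resp = p_hat[mask]
    if p_resp.size and (p_resp.min() <= 0.0 or p_resp.max() >= 1.0):
        raise InvalidProbabilityError(
            "fitted probabilities must lie strictly in (0, 1)")
    return 1.0 / p_resp


def _wls_beta(
    X: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve weighted least squares; returns (coef, (X'WX)^-1, residuals)."""
    Xw = X * w[:, None]
    A = Xw.T @ X
    b = Xw.T @ y
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("rank-deficient association design") from exc
    coef = A_inv @ b
    resid = y - X @ coef
    return coef, A_inv, resid


def wald_ci(beta_hat: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normality-based confidence interval beta_hat -/+ z_{1-(1-level)/2}*se."""
    if se <= 0.0:
        raise ValueError(f"se must be > 0, got {se}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    z = norm.ppf(0.5 + level / 2.0)
    return beta_hat - z * se, beta_hat + z * se


# intercept + 3 slopes, plus one residual degree of freedom for the SE
_MIN_RESPONDENTS = 5


def _association_design(sample: CohortSample) -> tuple[np.ndarray, np.ndarray]:
    mask = sample.respondent_mask
    if int(mask.sum()) < _MIN_RESPONDENTS:
        raise DegenerateDesignError(
            f"only {int(mask.sum())} respondents; need >= {_MIN_RESPONDENTS}"
        )
    X = _design_from_sample(sample, ASSOCIATION_TERMS)[mask]
    y = sample.y[mask]
    return X, y


def fit_association_cca(sample: CohortSample, level: float = 0.95) -> EstimateRecord:
    """Complete-case OLS of y on (1, x, z1, z5) among respondents.

    The reported standard error is the classical model-based OLS one.
    """
    X, y = _association_design(sample)
    m, k = X.shape
    coef, A_inv, resid = _wls_beta(X, y, np.ones(m))
    sigma2 = float(resid @ resid) / (m - k)
    se = float(np.sqrt(sigma2 * A_inv[1, 1]))
    lo, hi = wald_ci(coef[1], se, level)
    return EstimateRecord(
        estimator_label="CCA",
        beta_hat=float(coef[1]),
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        n_respondents=m,
    )


def _ippw_se(
    X: np.ndarray, w: np.ndarray, A_inv: np.ndarray, resid: np.ndarray,
    se_method: str,
) -> float:
    if se_method == "sandwich":
        # HC0 sandwich with weights treated as fixed:
        # (X'WX)^-1 [sum w_i^2 e_i^2 x_i x_i'] (X'WX)^-1
        Xe = X * (w * resid)[:, None]
        meat = Xe.T @ Xe
        V = A_inv @ meat @ A_inv
        return float(np.sqrt(V[1, 1]))
    if se_method == "model":
        m, k = X.shape
        sigma2 = float(w @ resid**2) / (m - k)
        return float(np.sqrt(sigma2 * A_inv[1, 1]))
    raise ValueError(
        f"unknown se_method {se_method!r}; available: 'sandwich', 'model' "
        "(a linearization estimator accounting for weight estimation may be "
        "registered under a new label)"
    )


def fit_association_ippw(
    sample: CohortSample,
    spec: ResponseModelSpec,
    se_method: str = "sandwich",
    level: float = 0.95,
    weight_cap: float | None = None,
) -> EstimateRecord:
    """IPPW: logistic response model -> weights -> weighted least squares.

    ``weight_cap`` optionally truncates weights from above; the default is
    no truncation (the maximum weight is always reported in
    ``weight_summary``).
    """
    fit = fit_response_model(sample, spec)
    w = compute_weights(fit.p_hat, sample.r)
    if weight_cap is not None:
        w = np.minimum(w, weight_cap)
    X, y = _association_design(sample)
    coef, A_inv, resid = _wls_beta(X, y, w)
    se = _ippw_se(X, w, A_inv, resid, se_method)
    lo, hi = wald_ci(coef[1], se, level)
    return EstimateRecord(
        estimator_label=spec.label,
        beta_hat=float(coef[1]),
        se=se,
        ci_lower=lo,
        ci_upper=hi,
        n_respondents=X.shape[0],
        response_fit_converged=fit.converged,
        weight_summary=(float(w.min()), float(w.max()), float(w.mean())),
    )


# ---------------------------------------------------------------------------
# Applied mode: frame-based estimation with a tiny formula grammar.
# ---------------------------------------------------------------------------

def parse_formula(formula: str) -> tuple[str, list[str]]:
    """Parse ``"lhs ~ t1 + t2 + ..."`` into (lhs, [terms]).

    Only additive terms of plain column names are supported; ``1`` denotes
    the intercept (always included), so ``"r ~ 1"`` is an intercept-only
    model.  This is the entire grammar of applied mode.
    """
    if "~" not in formula:
        raise ValueError(f"formula needs a '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    lhs = lhs.strip()
    raw = [t.strip() for t in rhs.split("+") if t.strip()]
    if not lhs or not raw:
        raise ValueError(f"malformed formula: {formula!r}")
    terms = [t for t in raw if t != "1"]
    return lhs, terms


def _frame_design(df, terms: list[str], rows=None) -> np.ndarray:
    missing = [t for t in terms if t not in df.columns]
    if missing:
        raise ValueError(f"columns not in data: {missing}")
    n_rows = len(rows) if rows is not None else len(df)
    if not terms:
        return np.ones((n_rows, 1))
    sub = df.loc[rows, terms] if rows is not None else df[terms]
    vals = sub.to_numpy(dtype=float)
    if np.isnan(vals).any():
        bad = [t for t in terms if np.isnan(sub[t].to_numpy(dtype=float)).any()]
        raise ValueError(
            f"missing values in covariates {bad}: applied mode does not impute"
        )
    return np.column_stack([np.ones(vals.shape[0]), vals])


def _frame_response(df, response_col: str) -> np.ndarray:
    if response_col not in df.columns:
        raise ValueError(f"response column {response_col!r} not in data")
    r = df[response_col].to_numpy(dtype=float)
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError(f"response column {response_col!r} must be binary 0/1")
    return r


def fit_cca_frame(
    df, association_formula: str, level: float = 0.95,
    response_col: str | None = None,
) -> EstimateRecord:
    """Complete-case OLS on a user table.

    Rows are complete cases of the association formula; if ``response_col``
    is given, rows flagged as non-respondents are excluded even when their
    outcome happens to be filled in.
    """
    ycol, terms = parse_formula(association_formula)
    yv = df[ycol].to_numpy(dtype=float)
    mask = ~np.isnan(yv)
    if response_col is not None:
        mask &= _frame_response(df, response_col).astype(bool)
    m = int(mask.sum())
    if m < len(terms) + 1:
        raise DegenerateDesignError(f"only {m} complete cases")
    X = _frame_design(df, terms, rows=df.index[mask])
    coef, A_inv, resid = _wls_beta(X, yv[mask], np.ones(m))
    sigma2 = float(resid @ resid) / (m - X.shape[1])
    se = float(np.sqrt(sigma2 * A_inv[1, 1]))
    lo, hi = wald_ci(coef[1], se, level)
    return EstimateRecord("CCA", float(coef[1]), se, lo, hi, m)


def fit_ippw_frame(
    df,
    response_formula: str,
    association_formula: str,
    se_method: str = "sandwich",
    level: float = 0.95,
    label: str | None = None,
) -> EstimateRecord:
    """IPPW on a user table: ``response_formula`` like ``"r ~ z1 + z2"``
    (fitted on all rows), ``association_formula`` like ``"y ~ x + z1 + z5"``
    (weighted fit on respondents)."""
    rcol, rterms = parse_formula(response_formula)
    ycol, aterms = parse_formula(association_formula)
    r = _frame_response(df, rcol)
    if ycol in rterms:
        raise ValueError(
            f"outcome {ycol!r} cannot be a response-model regressor: it is "
            "unobserved for non-respondents"
        )
    n_resp = int(r.sum())
    if n_resp == 0 or n_resp == len(r):
        raise DegenerateResponseError(f"{n_resp} of {len(r)} responded")
    Xr = _frame_design(df, rterms)
    coef, converged, n_iter = fit_logistic(Xr, r)
    if not converged:
        raise ConvergenceError(f"response fit did not converge ({n_iter} iters)")
    p_hat = expit(Xr @ coef)
    mask = r.astype(bool)
    yv = df[ycol].to_numpy(dtype=float)
    observed = mask & ~np.isnan(yv)
    if observed.sum() < mask.sum():
        raise ValueError("respondents with missing outcome values in the data")
    w = compute_weights(p_hat, r)
    Xa = _frame_design(df, aterms, rows=df.index[mask])
    b, A_inv, resid = _wls_beta(Xa, yv[mask], w)
    se = _ippw_se(Xa, w, A_inv, resid, se_method)
    lo, hi = wald_ci(b[1], se, level)
    return EstimateRecord(
        label or f"IPPW({response_formula})",
        float(b[1]), se, lo, hi, int(mask.sum()),
        response_fit_converged=True,
        weight_summary=(float(w.min()), float(w.max()), float(w.mean())),
    )
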