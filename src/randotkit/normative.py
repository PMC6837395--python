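"""Proportional-odds (cumulative-logit) normative model of Randot Preschool scores.

The score ``R`` is an ordered categorical outcome over the seven categories
40 < 60 < 100 < 200 < 400 < 800 < nil.  The probability of scoring at or
better than a numeric level ``L`` is modelled as

    P(R <= L) = expit(alpha_L - beta*A - gamma*x_male - ...)

with six ordered cut-points ``alpha_L`` (one per adjacent-level boundary),
an age slope ``beta`` on a transformed age covariate ``A``, and an additive
male effect ``gamma`` (optionally further binary covariates).  Category
probabilities are differences of adjacent cumulative probabilities, with
P(nil) = 1 - P(R <= 800).  A negative ``beta`` with increasing ``A`` means
scores improve with age; a positive ``gamma`` means boys score worse.

The likelihood, its gradient, the monotone reparameterization of the
cut-points, and the delta-method standard errors are implemented here;
scipy only supplies the quasi-Newton optimizer.

Age transform
-------------
``A`` is configurable: ``log10_months`` (default for the published
reference parameters), ``log10_years`` or ``identity_years``.  The
published reference fit is only consistent with observed score
distributions under the log10-months convention even though its source
describes ``A`` as log10 years; every fit records the transform used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from .scores import LEVELS, NIL, ScoreError, StereoScore, score_rank

__all__ = [
    "OrdinalParams",
    "Covariates",
    "FitResult",
    "REFERENCE_PARAMS",
    "AGE_TRANSFORMS",
    "age_covariate",
    "cumulative_prob",
    "score_pmf",
    "ordinal_loglik",
    "fit_ordinal",
    "sample_score",
    "sample_scores",
    "FitError",
]

N_CUTS = len(LEVELS)  # six boundaries: 40|60 ... 800|nil
N_CATEGORIES = N_CUTS + 1

#: Supported transforms from age in years to the model covariate A.
AGE_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log10_months": lambda years: np.log10(12.0 * np.asarray(years, dtype=float)),
    "log10_years": lambda years: np.log10(np.asarray(years, dtype=float)),
    "identity_years": lambda years: np.asarray(years, dtype=float),
}


def age_covariate(age_years, transform: str = "log10_months") -> np.ndarray:
    """Apply a named age transform to ages in years."""
    try:
        fn = AGE_TRANSFORMS[transform]
    except KeyError:
        raise ValueError(
            f"unknown age transform {transform!r}; choose from {sorted(AGE_TRANSFORMS)}"
        ) from None
    return fn(age_years)


class FitError(RuntimeError):
    """Raised when the ordinal fit cannot produce a usable result."""


@dataclass(frozen=True)
class OrdinalParams:
    """Parameters of the cumulative-logit model.

    ``alphas`` are the six ordered cut-points on the logit scale, in level
    order (40|60 first, 800|nil last); ``beta`` is the age slope on the
    covariate ``A``; ``gamma`` the male effect; ``extras`` optional further
    covariate effects.
    """

    alphas: tuple[float, ...]
    beta: float
    gamma: float
    extras: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        alphas = tuple(float(a) for a in self.alphas)
        if len(alphas) != N_CUTS:
            raise ValueError(f"need {N_CUTS} cut-points, got {len(alphas)}")
        if not all(math.isfinite(a) for a in alphas):
            raise ValueError("cut-points must be finite")
        if any(b < a for a, b in zip(alphas, alphas[1:])):
            raise ValueError("cut-points must be nondecreasing")
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "extras", tuple(float(e) for e in self.extras))

    @property
    def coefficients(self) -> np.ndarray:
        """Covariate effects in design-matrix order: beta, gamma, extras."""
        return np.array([self.beta, self.gamma, *self.extras], dtype=float)


#: Published normative parameters for the Randot Preschool (UK cohort,
#: ages 2-11, 824 visually normal children), with the age covariate A
#: interpreted as log10(age in months) — see the module docstring.
REFERENCE_PARAMS = OrdinalParams(
    alphas=(-5.513, -4.623, -3.639, -2.679, -2.007, -0.9797),
    beta=-3.079,
    gamma=0.4152,
)


@dataclass(frozen=True)
class Covariates:
    """Covariate values for one child: transformed age A, male indicator, extras."""

    A: float
    x_male: int = 0
    extras: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.x_male not in (0, 1):
            raise ValueError("x_male must be 0 or 1")

    def vector(self) -> np.ndarray:
        return np.array([self.A, self.x_male, *self.extras], dtype=float)


def _linear_predictor(params: OrdinalParams, cov: Covariates) -> float:
    x = cov.vector()
    b = params.coefficients
    if x.size != b.size:
        raise ValueError(
            f"covariate vector has {x.size} entries but params define {b.size} effects"
        )
    return float(x @ b)


def cumulative_prob(params: OrdinalParams, cov: Covariates, level: int) -> float:
    """P(R <= level): probability of scoring at or better than *level*.

    *level* must be one of the six numeric levels; nil is the complement of
    the 800-arcsec cumulative category, not a cumulative category itself.
    """
    if level not in LEVELS:
        raise ScoreError(
            f"level must be one of {LEVELS}; nil/NT are not cumulative categories"
        )
    idx = LEVELS.index(level)
    return float(expit(params.alphas[idx] - _linear_predictor(params, cov)))


def score_pmf(params: OrdinalParams, cov: Covariates) -> np.ndarray:
    """Probability of each of the seven categories (40, ..., 800, nil).

    Entries are differences of adjacent cumulative probabilities and sum to
    one exactly (the sum telescopes).
    """
    xb = _linear_predictor(params, cov)
    cum = expit(np.asarray(params.alphas) - xb)
    pmf = np.diff(np.concatenate(([0.0], cum, [1.0])))
    return pmf


def sample_score(
    params: OrdinalParams, cov: Covariates, rng: np.random.Generator
) -> StereoScore:
    """Draw one score from the model by inverse-CDF sampling."""
    xb = _linear_predictor(params, cov)
    return _draw(params, np.array([xb]), rng)[0]


def sample_scores(
    params: OrdinalParams,
    age_years,
    x_male,
    rng: np.random.Generator,
    transform: str = "log10_months",
) -> list[StereoScore]:
    """Vectorized inverse-CDF sampling for arrays of ages and sex indicators."""
    A = age_covariate(age_years, transform)
    x_male = np.asarray(x_male, dtype=float)
    xb = params.beta * A + params.gamma * x_male
    return _draw(params, xb, rng)


def _draw(params: OrdinalParams, xb: np.ndarray, rng: np.random.Generator) -> list:
    cum = expit(np.asarray(params.alphas)[None, :] - xb[:, None])  # (n, 6)
    u = rng.random(xb.size)
    idx = (u[:, None] > cum).sum(axis=1)  # 0..6
    categories = list(LEVELS) + [NIL]
    return [categories[i] for i in idx]


# ---------------------------------------------------------------------------
# Likelihood


def _prepare_data(
    scores: Sequence[StereoScore], X: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    cats = np.array([score_rank(s) for s in scores], dtype=np.intp)
    if X is None:
        X = np.empty((cats.size, 0))
    else:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != cats.size:
            raise ValueError("design matrix rows must match number of scores")
    return cats, X


def _category_probs(alphas: np.ndarray, xb: np.ndarray, cats: np.ndarray):
    """Per-record probability of the observed category plus pieces for the gradient."""
    cum = expit(alphas[None, :] - xb[:, None])  # (n, 6)
    dens = cum * (1.0 - cum)  # logistic density at each cut
    n = cats.size
    rows = np.arange(n)
    has_up = cats < N_CUTS
    has_lo = cats > 0
    cum_up = np.where(has_up, cum[rows, np.minimum(cats, N_CUTS - 1)], 1.0)
    cum_lo = np.where(has_lo, cum[rows, np.maximum(cats - 1, 0)], 0.0)
    f_up = np.where(has_up, dens[rows, np.minimum(cats, N_CUTS - 1)], 0.0)
    f_lo = np.where(has_lo, dens[rows, np.maximum(cats - 1, 0)], 0.0)
    p = cum_up - cum_lo
    return p, f_up, f_lo, has_up, has_lo


def ordinal_loglik(
    params: OrdinalParams,
    scores: Sequence[StereoScore],
    X: np.ndarray | None = None,
) -> float:
    """Log-likelihood of observed scores under the model.

    ``X`` is the design matrix (columns: A, x_male, extras) matching
    ``params.coefficients``; omit it for an intercept-only model.  Returns
    ``-inf`` when any observed category has probability zero.
    """
    cats, X = _prepare_data(scores, X)
    b = params.coefficients[: X.shape[1]] if X.shape[1] else np.empty(0)
    if X.shape[1] and X.shape[1] != params.coefficients.size:
        raise ValueError("design matrix width must match number of coefficients")
    xb = X @ b if X.shape[1] else np.zeros(cats.size)
    p, *_ = _category_probs(np.asarray(params.alphas), xb, cats)
    if np.any(p <= 0):
        return float("-inf")
    return float(np.sum(np.log(p)))


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Unconstrained theta -> (monotone alphas, coefficients)."""
    a1 = theta[0]
    gaps = np.exp(theta[1:N_CUTS])
    alphas = a1 + np.concatenate(([0.0], np.cumsum(gaps)))
    return alphas, theta[N_CUTS : N_CUTS + k]


def _neg_loglik_and_grad(theta: np.ndarray, cats: np.ndarray, X: np.ndarray):
    k = X.shape[1]
    alphas, b = _unpack(theta, k)
    xb = X @ b if k else np.zeros(cats.size)
    p, f_up, f_lo, has_up, has_lo = _category_probs(alphas, xb, cats)
    p = np.maximum(p, 1e-300)
    nll = -float(np.sum(np.log(p)))

    w_up = f_up / p
    w_lo = f_lo / p
    g_alpha = np.bincount(
        cats[has_up], weights=w_up[has_up], minlength=N_CUTS
    ) - np.bincount(cats[has_lo] - 1, weights=w_lo[has_lo], minlength=N_CUTS)
    grad = np.empty_like(theta)
    grad[0] = g_alpha.sum()
    # gap m (1-based cut index) feeds every alpha_j with j >= m
    tail = np.cumsum(g_alpha[::-1])[::-1]
    grad[1:N_CUTS] = np.exp(theta[1:N_CUTS]) * tail[1:]
    if k:
        grad[N_CUTS:] = -X.T @ (w_up - w_lo)
    return nll, -grad


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of the cumulative-logit model."""

    params: OrdinalParams
    param_names: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    loglik: float
    n: int
    converged: bool
    grad_norm: float
    empty_categories: tuple[int, ...] = ()
    age_transform: str | None = None
    message: str = ""

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    def summary_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "std_error": self.standard_errors,
                "p_value": self.p_values,
            },
            index=list(self.param_names),
        )


def _start_values(cats: np.ndarray, k: int) -> np.ndarray:
    n = cats.size
    counts = np.bincount(cats, minlength=N_CATEGORIES)
    cum = np.cumsum(counts)[:N_CUTS] / n
    cum = np.clip(cum, 0.5 / n, 1.0 - 0.5 / n)
    a = logit(cum)
    a = np.maximum.accumulate(a)
    gaps = np.maximum(np.diff(a), 1e-3)
    return np.concatenate(([a[0]], np.log(gaps), np.zeros(k)))


def _hessian(theta: np.ndarray, cats: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of the negative log-likelihood."""
    d = theta.size
    H = np.empty((d, d))
    for j in range(d):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, gp = _neg_loglik_and_grad(tp, cats, X)
        _, gm = _neg_loglik_and_grad(tm, cats, X)
        H[j] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _constrained_jacobian(theta: np.ndarray, k: int) -> np.ndarray:
    """d(alphas, coefs)/d(theta) for the delta method."""
    d = theta.size
    J = np.zeros((d, d))
    J[:N_CUTS, 0] = 1.0
    for m in range(1, N_CUTS):
        J[m:N_CUTS, m] = np.exp(theta[m])
    for j in range(k):
        J[N_CUTS + j, N_CUTS + j] = 1.0
    return J


def fit_ordinal(
    scores: Sequence[StereoScore],
    X: np.ndarray | None = None,
    feature_names: Sequence[str] | None = None,
    n_starts: int = 3,
    gtol: float = 1e-8,
    seed: int = 0,
    age_transform: str | None = None,
) -> FitResult:
    """Fit the cumulative-logit model by maximum likelihood.

    Parameters
    ----------
    scores : observed scores (numeric levels or nil; NOT_TESTABLE must be
        excluded upstream).
    X : design matrix, one row per score.  Column order defines the
        coefficient order (conventionally A first, then the male indicator).
        None or zero columns fits an intercept-only model, whose MLE is the
        empirical cumulative logits.
    n_starts : number of optimizer starts (first from empirical cumulative
        logits, the rest jittered) to guard against local optima.

    Monotone cut-points are enforced by reparameterization (first cut free,
    subsequent gaps as exponentials); standard errors are delta-method
    transforms of the inverse observed information.
    """
    cats, X = _prepare_data(scores, X)
    n, k = cats.size, X.shape[1]
    counts = np.bincount(cats, minlength=N_CATEGORIES)
    if np.count_nonzero(counts) < 2:
        raise FitError("need at least two distinct observed categories")
    if n <= N_CUTS + k:
        raise FitError(f"n={n} too small to fit {N_CUTS + k} parameters")

    rng = np.random.default_rng(seed)
    theta0 = _start_values(cats, k)
    best = None
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.5, theta0.size)
        res = minimize(
            _neg_loglik_and_grad,
            start,
            args=(cats, X),
            jac=True,
            method="L-BFGS-B",
            options={"gtol": gtol, "ftol": 1e-14, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = best.x
    if not np.all(np.isfinite(theta)):
        raise FitError("optimizer diverged to non-finite parameters")
    alphas, b = _unpack(theta, k)
    if k and np.any(np.abs(b) > 30):
        raise FitError(
            "covariate effect diverged (|coef| > 30): data are likely "
            "completely separated"
        )

    beta = float(b[0]) if k >= 1 else 0.0
    gamma = float(b[1]) if k >= 2 else 0.0
    extras = tuple(float(v) for v in b[2:])
    params = OrdinalParams(alphas=tuple(alphas), beta=beta, gamma=gamma, extras=extras)

    H = _hessian(theta, cats, X)
    try:
        cov_theta = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_theta = np.linalg.pinv(H)
    J = _constrained_jacobian(theta, k)
    cov = J @ cov_theta @ J.T
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    se = np.sqrt(var)

    estimates = np.concatenate([alphas, b])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = estimates / se
        p_values = 2.0 * norm.sf(np.abs(z))

    cut_names = tuple(
        f"alpha_{lo}|{'nil' if hi is None else hi}"
        for lo, hi in zip(LEVELS, list(LEVELS[1:]) + [None])
    )
    if feature_names is None:
        feature_names = ["beta", "gamma", *[f"extra_{i}" for i in range(k - 2)]][:k]
    names = cut_names + tuple(feature_names)

    _, neg_grad = _neg_loglik_and_grad(theta, cats, X)
    grad_norm = float(np.max(np.abs(neg_grad)))
    converged = bool(best.success) or grad_norm < 1e-5 * (1.0 + abs(best.fun))
    return FitResult(
        params=params,
        param_names=names,
        estimates=estimates,
        standard_errors=se,
        p_values=p_values,
        loglik=-float(best.fun),
        n=n,
        converged=converged,
        grad_norm=grad_norm,
        empty_categories=tuple(int(i) for i in np.flatnonzero(counts == 0)),
        age_transform=age_transform,
        message=str(best.message),
    )


def params_to_dict(params: OrdinalParams, age_transform: str | None = None) -> dict:
    """JSON-ready representation of parameters (records the age transform)."""
    return {
        "alphas": list(params.alphas),
        "beta": params.beta,
        "gamma": params.gamma,
        "extras": list(params.extras),
        "age_transform": age_transform,
    }


def params_from_dict(d: dict) -> tuple[OrdinalParams, str | None]:
    """Inverse of :func:`params_to_dict`."""
    params = OrdinalParams(
        alphas=tuple(d["alphas"]),
        beta=float(d["beta"]),
        gamma=float(d["gamma"]),
        extras=tuple(d.get("extras", ())),
    )
    return params, d.get("age_transform")
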