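"""Hyperbolic subjective-value models, choice likelihood and per-subject fits.

Both tasks use the same one-parameter hyperbolic discount applied to the
subject's own perception rating of the discounting attribute:

    SV = magnitude / (1 + K * rating)

with ``magnitude`` the larger-later amount (CHF) or the number of lives
saved, and ``rating`` the subject's 0–100 perception of the delay or of the
deservingness of the person at stake.  K is the per-subject discount
constant, in units of 1/rating.  The reference option (20 CHF today; sparing
the one person) is not discounted, so its value is fixed at 20 CHF / 1 life.

Choices follow a logistic (softmax) rule on the SV difference,

    P(choose target) = 1 / (1 + exp(-beta * (SV_target - SV_reference)))

with a per-subject, per-task choice temperature ``beta`` (inverse noise, in
1/SV units).  Per-subject (K, beta) are estimated by bounded maximum
likelihood with multiple starting points on K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .data import ChoiceDataset
from .errors import ValidationError

__all__ = [
    "FitResult",
    "SlopeResult",
    "sv_financial",
    "sv_moral",
    "dataset_svs",
    "choice_loglik",
    "fit_subject",
    "grid_search_fit",
    "discount_curve_r2",
    "choice_slope",
    "rt_slope",
]

#: Probability clip used in the likelihood so it never returns -inf.
_P_EPS = 1e-12

#: Default bounds for the bounded MLE.  The K interval covers both printed
#: population ranges (3.78e-5..0.043 and 0.093..7.08) with ample margin.
DEFAULT_K_BOUNDS = (1e-6, 20.0)
DEFAULT_BETA_BOUNDS = (0.0, 100.0)


def _hyperbolic_sv(magnitude, k, rating):
    magnitude = np.asarray(magnitude, dtype=float)
    rating = np.asarray(rating, dtype=float)
    k = float(k)
    if np.any(magnitude < 0) or np.any(rating < 0) or k < 0:
        raise ValidationError("magnitude, discount constant and rating must be >= 0")
    return magnitude / (1.0 + k * rating)


def sv_financial(amount, k_f, delay_rating):
    """Subjective value (CHF) of a larger-later reward.

    ``amount`` is the delayed amount LL, ``k_f`` the financial discount
    constant and ``delay_rating`` the subject's 0–100 rating of the delay.
    Equals LL when ``k_f * delay_rating == 0`` and decreases in both.
    """
    return _hyperbolic_sv(amount, k_f, delay_rating)


def sv_moral(lives, k_m, deservingness_rating):
    """Subjective moral value (life-equivalents) of saving the larger group.

    Structurally identical to :func:`sv_financial`: the number of lives
    saved is discounted by the perceived deservingness of the person who
    would be sacrificed.
    """
    return _hyperbolic_sv(lives, k_m, deservingness_rating)


def dataset_svs(dataset: ChoiceDataset, k: float) -> np.ndarray:
    """Recompute per-trial target SVs from the stored attributes under ``k``."""
    return _hyperbolic_sv(
        dataset.trials["magnitude"].to_numpy(),
        k,
        dataset.trials["perceived"].to_numpy(),
    )


def _loglik_arrays(k, beta, magnitude, rating, chose, ref):
    sv = magnitude / (1.0 + k * rating)
    z = beta * (sv - ref)
    # log P(choice): log_expit(z) for target choices, log_expit(-z) otherwise
    ll = np.where(chose, log_expit(z), log_expit(-z))
    floor = np.log(_P_EPS)
    return float(np.sum(np.maximum(ll, floor)))


def choice_loglik(k: float, beta: float, dataset: ChoiceDataset) -> float:
    """Sum of log choice probabilities (nats) under the logistic-SV rule.

    Probabilities are clipped to [1e-12, 1 - 1e-12], so the result is
    finite for any admissible (k, beta).
    """
    if not np.isfinite(k) or not np.isfinite(beta):
        raise ValidationError("k and beta must be finite")
    if k < 0 or beta < 0:
        raise ValidationError("k and beta must be non-negative")
    t = dataset.trials
    return _loglik_arrays(
        float(k),
        float(beta),
        t["magnitude"].to_numpy(dtype=float),
        t["perceived"].to_numpy(dtype=float),
        t["chose_target"].to_numpy(dtype=bool),
        dataset.reference_value,
    )


@dataclass
class FitResult:
    """Maximum-likelihood estimates for one subject and task."""

    k_hat: float
    beta_hat: float
    loglik: float
    converged: bool
    n_trials: int
    discount_r2: float
    se_k: float | None = None
    starts_used: int = 0
    identifiable: bool = True


@dataclass
class SlopeResult:
    """Standardized regression slope of choice or RT on subjective value."""

    beta0: float
    beta1: float
    kind: str  # "choice_logistic" or "rt_linear"


def _neg_loglik_factory(dataset: ChoiceDataset):
    t = dataset.trials
    magnitude = t["magnitude"].to_numpy(dtype=float)
    rating = t["perceived"].to_numpy(dtype=float)
    chose = t["chose_target"].to_numpy(dtype=bool)
    ref = dataset.reference_value

    def neg_loglik(params):
        log_k, beta = params
        return -_loglik_arrays(np.exp(log_k), beta, magnitude, rating, chose, ref)

    return neg_loglik


def fit_subject(
    dataset: ChoiceDataset,
    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS,
    beta_bounds: tuple[float, float] = DEFAULT_BETA_BOUNDS,
    n_starts: int = 10,
    seed: int | None = None,
    compute_r2: bool = True,
) -> FitResult:
    """Fit (K, beta) by bounded L-BFGS-B with log-spaced multi-starts on K.

    Deterministic given ``seed`` (the seed only jitters the beta starting
    values).  Non-identifiable datasets (all choices identical) are fitted
    anyway — K typically lands on a bound — and flagged with a warning and
    ``identifiable=False``.
    """
    if dataset.n_trials == 0:
        raise ValidationError("cannot fit an empty dataset")
    if k_bounds[0] <= 0 or k_bounds[0] >= k_bounds[1]:
        raise ValidationError("k_bounds must satisfy 0 < lower < upper")

    chose = dataset.trials["chose_target"].to_numpy(dtype=bool)
    identifiable = bool(chose.any() and not chose.all())
    if not identifiable:
        warnings.warn(
            f"subject {dataset.subject_id} ({dataset.task}): all choices identical; "
            "the discount constant is not identifiable",
            stacklevel=2,
        )

    neg_loglik = _neg_loglik_factory(dataset)
    rng = np.random.default_rng(seed)
    log_k_starts = np.linspace(np.log(k_bounds[0]), np.log(k_bounds[1]), n_starts)

    # heuristic beta start: unit slope on the standardized SV scale
    def beta_start(log_k):
        sv = dataset_svs(dataset, np.exp(log_k))
        spread = np.std(sv - dataset.reference_value)
        base = 1.0 / spread if spread > 0 else 1.0
        jitter = rng.uniform(0.5, 2.0) if seed is not None else 1.0
        return float(np.clip(base * jitter, beta_bounds[0] + 1e-6, beta_bounds[1]))

    bounds = [
        (np.log(k_bounds[0]), np.log(k_bounds[1])),
        (beta_bounds[0], beta_bounds[1]),
    ]
    best = None
    any_success = False
    for log_k0 in log_k_starts:
        res = minimize(
            neg_loglik,
            x0=np.array([log_k0, beta_start(log_k0)]),
            method="L-BFGS-B",
            bounds=bounds,
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    k_hat = float(np.exp(best.x[0]))
    beta_hat = float(best.x[1])
    loglik = -float(best.fun)
    se_k = _se_k(neg_loglik, best.x) if identifiable else None
    r2 = float("nan")
    if compute_r2:
        r2 = discount_curve_r2(k_hat, beta_hat, dataset)
    return FitResult(
        k_hat=k_hat,
        beta_hat=beta_hat,
        loglik=loglik,
        converged=any_success,
        n_trials=dataset.n_trials,
        discount_r2=r2,
        se_k=se_k,
        starts_used=n_starts,
        identifiable=identifiable,
    )


def _se_k(neg_loglik, x_hat, h=1e-4):
    """Delta-method standard error of K from a finite-difference Hessian."""
    try:
        hess = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                e_i = np.zeros(2)
                e_j = np.zeros(2)
                e_i[i] = h
                e_j[j] = h
                hess[i, j] = (
                    neg_loglik(x_hat + e_i + e_j)
                    - neg_loglik(x_hat + e_i - e_j)
                    - neg_loglik(x_hat - e_i + e_j)
                    + neg_loglik(x_hat - e_i - e_j)
                ) / (4.0 * h * h)
        cov = np.linalg.inv(hess)
        var_log_k = cov[0, 0]
        if var_log_k <= 0:
            return None
        # var(K) = K^2 var(log K)
        return float(np.exp(x_hat[0]) * np.sqrt(var_log_k))
    except np.linalg.LinAlgError:
        return None


def grid_search_fit(
    dataset: ChoiceDataset,
    n_k: int = 200,
    n_beta: int = 200,
    k_bounds: tuple[float, float] = DEFAULT_K_BOUNDS,
    beta_bounds: tuple[float, float] = (1e-2, 100.0),
) -> tuple[float, float, float]:
    """Exhaustive log-grid reference fit: returns (k, beta, loglik).

    Brute force over an ``n_k`` x ``n_beta`` log-spaced grid, fully
    vectorized.  Intended as an optimizer-independent reference, not for
    routine use.
    """
    t = dataset.trials
    magnitude = t["magnitude"].to_numpy(dtype=float)
    rating = t["perceived"].to_numpy(dtype=float)
    chose = t["chose_target"].to_numpy(dtype=bool)
    ref = dataset.reference_value

    ks = np.exp(np.linspace(np.log(k_bounds[0]), np.log(k_bounds[1]), n_k))
    betas = np.exp(np.linspace(np.log(beta_bounds[0]), np.log(beta_bounds[1]), n_beta))

    # (n_k, n_trials) SV differences
    dsv = magnitude[None, :] / (1.0 + ks[:, None] * rating[None, :]) - ref
    sign = np.where(chose, 1.0, -1.0)[None, None, :]
    z = betas[None, :, None] * dsv[:, None, :] * sign
    ll = np.maximum(log_expit(z), np.log(_P_EPS)).sum(axis=2)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(ks[i]), float(betas[j]), float(ll[i, j])


def discount_curve_r2(
    k: float,
    beta: float,
    dataset: ChoiceDataset,
    method: str = "proportions",
) -> float:
    """Goodness of fit of the discount model to the observed choice pattern.

    ``method="proportions"`` (default): R² = 1 − SS_res/SS_tot comparing the
    model-predicted choice probability of each (magnitude × level) cell with
    the empirical cell choice proportion.  ``method="indifference"``
    compares model and empirical indifference magnitudes per level (the
    empirical point is linearly interpolated from the cell proportions;
    levels whose proportions never cross 0.5 are skipped).

    Returns NaN when the statistic is undefined (fewer than two cells, or
    zero variance of the empirical values).
    """
    t = dataset.trials
    cells = (
        t.assign(sv=dataset_svs(dataset, k))
        .groupby(["magnitude", "level"])
        .agg(p_emp=("chose_target", "mean"), sv=("sv", "first"), perceived=("perceived", "first"))
        .reset_index()
    )
    if method == "proportions":
        if len(cells) < 2:
            return float("nan")
        p_mod = expit(beta * (cells["sv"].to_numpy() - dataset.reference_value))
        p_emp = cells["p_emp"].to_numpy()
        ss_tot = float(np.sum((p_emp - p_emp.mean()) ** 2))
        if ss_tot <= 0:
            return float("nan")
        ss_res = float(np.sum((p_emp - p_mod) ** 2))
        return 1.0 - ss_res / ss_tot
    if method == "indifference":
        return _indifference_r2(k, cells, dataset.reference_value)
    raise ValidationError(f"unknown r2 method {method!r}")


def _indifference_r2(k, cells, ref):
    emp, mod = [], []
    for level, grp in cells.groupby("level"):
        grp = grp.sort_values("magnitude")
        p = grp["p_emp"].to_numpy()
        m = grp["magnitude"].to_numpy(dtype=float)
        crossings = np.nonzero((p[:-1] - 0.5) * (p[1:] - 0.5) <= 0)[0]
        if len(crossings) == 0 or len(m) < 2:
            continue
        i = crossings[0]
        if p[i + 1] == p[i]:
            m_star = 0.5 * (m[i] + m[i + 1])
        else:
            m_star = m[i] + (0.5 - p[i]) * (m[i + 1] - m[i]) / (p[i + 1] - p[i])
        perceived = float(grp["perceived"].iloc[0])
        emp.append(m_star)
        # model indifference: the magnitude whose SV equals the reference
        mod.append(ref * (1.0 + k * perceived))
    emp = np.asarray(emp)
    mod = np.asarray(mod)
    if len(emp) < 2:
        return float("nan")
    ss_tot = float(np.sum((emp - emp.mean()) ** 2))
    if ss_tot <= 0:
        return float("nan")
    return 1.0 - float(np.sum((emp - mod) ** 2)) / ss_tot


def _standardized_sv(dataset: ChoiceDataset) -> np.ndarray:
    sv = dataset.trials["sv_target"].to_numpy(dtype=float)
    sd = sv.std()
    if sd == 0:
        raise ValidationError("subjective values have zero variance")
    return (sv - sv.mean()) / sd


def choice_slope(dataset: ChoiceDataset) -> SlopeResult:
    """Standardized slope of the logistic regression of choice on SV.

    SV is standardized within subject (mean 0, sd 1).  Estimated by
    Firth's bias-reduced penalized likelihood (Jeffreys-prior penalty),
    which removes the leading-order small-sample bias of the plain MLE and
    keeps the estimate finite when choices are perfectly separable — which
    routinely happens for low-noise subjects.  For well-conditioned data
    the estimate is indistinguishable from the ordinary MLE.
    """
    z = _standardized_sv(dataset)
    y = dataset.trials["chose_target"].to_numpy(dtype=float)
    x = np.column_stack([np.ones_like(z), z])

    def neg_penalized(params):
        eta = x @ params
        ll = np.sum(y * log_expit(eta) + (1.0 - y) * log_expit(-eta))
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-10, None)
        xtwx = x.T @ (x * w[:, None])
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            return -ll + 1e6
        return -(ll + 0.5 * logdet)

    res = minimize(neg_penalized, x0=np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    return SlopeResult(beta0=float(res.x[0]), beta1=float(res.x[1]), kind="choice_logistic")


def rt_slope(dataset: ChoiceDataset) -> SlopeResult:
    """Slope of the linear regression RT = b0 + b1 * SV (SV standardized)."""
    import statsmodels.api as sm

    z = _standardized_sv(dataset)
    rt = dataset.trials["rt_ms"].to_numpy(dtype=float)
    model = sm.OLS(rt, sm.add_constant(z)).fit()
    return SlopeResult(beta0=float(model.params[0]), beta1=float(model.params[1]), kind="rt_linear")
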