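"""Maximum-likelihood estimation of the progressive CTMC from panel data.

The likelihood conditions on each patient's first observed state and
multiplies interval transition probabilities over consecutive visit
pairs.  Because time-dependent covariates are frozen at each visit's
value until the next visit, every inter-visit interval is a homogeneous
chain and its probability is a single matrix exponential of the
interval generator; the full likelihood therefore vectorizes into one
batched exponential over all intervals in the cohort.

Parameters are optimized as unconstrained log intensities (plus shared
covariate coefficients) by L-BFGS-B; the covariance is the inverse of
the numerical Hessian at the optimum, hazard-ratio inference is Wald,
model selection is AIC backward elimination with full refits, and
confidence intervals for derived probabilities come from a parametric
bootstrap (normal resampling of the MLE).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from ._expm import expm_batch
from .cohort import BINARY_COVARIATES, TIME_DEPENDENT, Cohort, PatientSeries
from .ctmc import (
    TRANSITIONS,
    CovariateModel,
    CovariateSchedule,
    generator_from_rates,
    pdr_probability,
)

N_TRANS = len(TRANSITIONS)

THETA_BOUNDS = (-12.0, 3.0)
BETA_BOUNDS = (-6.0, 6.0)

#: Covariates that are carried on the original scale (never mean-centered).
_UNCENTERED = BINARY_COVARIATES | {"anti_vegf_count"}


class RegressionError(ValueError):
    """A recorded stage regression makes an interval probability zero."""


class FitError(RuntimeError):
    """The optimizer failed to converge."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class IntervalData:
    """Vectorized likelihood inputs: one row per inter-visit interval."""

    dt: np.ndarray          # (m,) interval lengths in years
    Z: np.ndarray           # (m, k) centered covariates at the interval start
    s0: np.ndarray          # (m,) state at interval start, 1-based
    s1: np.ndarray          # (m,) state at interval end, 1-based
    covariates: tuple[str, ...]
    centering: dict[str, float]
    n_patients: int

    @property
    def n_intervals(self) -> int:
        return len(self.dt)


def default_centering(cohort: Cohort, covariates: Sequence[str]) -> dict[str, float]:
    """Cohort-mean centering for continuous covariates, 0 for indicators."""
    out = {}
    for name in covariates:
        if name in _UNCENTERED:
            out[name] = 0.0
        else:
            vals = cohort.covariate_values(name)
            out[name] = float(vals.mean()) if len(vals) else 0.0
    return out


def _interval_covariates(p: PatientSeries, j: int, covariates: Sequence[str]) -> list[float]:
    row = []
    for name in covariates:
        if name in TIME_DEPENDENT:
            row.append(float(getattr(p.visits[j], name)))
        else:
            row.append(p.baseline_value(name))
    return row


def build_interval_data(
    cohort: Cohort,
    covariates: Sequence[str] = (),
    centering: Mapping[str, float] | None = None,
) -> IntervalData:
    """Extract likelihood intervals from all eligible patients.

    Intervals beginning in the absorbing PDR state are dropped; a
    recorded regression raises :class:`RegressionError` (clamp stages
    first).  Covariates for the interval [t_j, t_{j+1}) are the values
    observed at t_j.
    """
    covariates = tuple(covariates)
    if centering is None:
        centering = default_centering(cohort, covariates)
    centering = {c: float(centering.get(c, 0.0)) for c in covariates}
    offsets = np.array([centering[c] for c in covariates])

    dt, Z, s0, s1 = [], [], [], []
    n_pat = 0
    for p in cohort.eligible_patients():
        stages, times = p.stages, p.times
        used = False
        for j in range(len(p.visits) - 1):
            a, b = int(stages[j]), int(stages[j + 1])
            if a == 5:
                continue
            if b < a:
                raise RegressionError(
                    f"patient {p.patient_id}: stage regressed from {a} to {b} over "
                    f"[{times[j]:g}, {times[j + 1]:g}]; enforce monotone stages first"
                )
            row = _interval_covariates(p, j, covariates)
            if any(np.isnan(row)):
                raise ValueError(
                    f"patient {p.patient_id}: missing covariate values at t={times[j]:g}; "
                    "impute before fitting"
                )
            dt.append(times[j + 1] - times[j])
            Z.append(row)
            s0.append(a)
            s1.append(b)
            used = True
        n_pat += used
    if not dt:
        raise ValueError("no usable intervals in cohort")
    Z_arr = np.asarray(Z, dtype=float).reshape(len(dt), len(covariates))
    return IntervalData(
        dt=np.asarray(dt),
        Z=Z_arr - offsets,
        s0=np.asarray(s0),
        s1=np.asarray(s1),
        covariates=covariates,
        centering=centering,
        n_patients=int(n_pat),
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _interval_log_probs(params: np.ndarray, data: IntervalData) -> np.ndarray:
    theta, beta = params[:N_TRANS], params[N_TRANS:]
    lp = data.Z @ beta if len(beta) else np.zeros(data.n_intervals)
    q = np.exp(theta[None, :] + lp[:, None])
    Q = generator_from_rates(q)
    P = expm_batch(Q * data.dt[:, None, None])
    p = P[np.arange(data.n_intervals), data.s0 - 1, data.s1 - 1]
    return np.log(np.clip(p, 1e-300, None))


def _negloglik(params: np.ndarray, data: IntervalData) -> float:
    return -float(_interval_log_probs(params, data).sum())


def _negloglik_grad(params: np.ndarray, data: IntervalData) -> tuple[float, np.ndarray]:
    """Value and exact gradient of the negative log-likelihood.

    Uses the Fréchet-derivative adjoint of the matrix exponential: for
    each interval, expm of the 10x10 block matrix [[A^T, W], [0, A^T]]
    (W the indicator of the observed transition entry) returns both
    P = expm(A) and the sensitivity G = L*(A, W) of the observed entry
    to every generator entry, so one batched exponential yields the
    whole gradient.
    """
    from .ctmc import N_STATES, _COL_IDX, _ROW_IDX

    theta, beta = params[:N_TRANS], params[N_TRANS:]
    m = data.n_intervals
    lp = data.Z @ beta if len(beta) else np.zeros(m)
    q = np.exp(theta[None, :] + lp[:, None])           # (m, 10)
    A = generator_from_rates(q) * data.dt[:, None, None]

    n = N_STATES
    block = np.zeros((m, 2 * n, 2 * n))
    At = np.swapaxes(A, -1, -2)
    block[:, :n, :n] = At
    block[:, n:, n:] = At
    rows = np.arange(m)
    block[rows, data.s0 - 1, n + data.s1 - 1] = 1.0    # W = e_u e_v^T
    E = expm_batch(block)
    p = E[rows, data.s1 - 1, data.s0 - 1]              # [expm(A^T)]_{v,u} = P_{u,v}
    G = E[:, :n, n:]                                   # L*(A, W), shape (m, 5, 5)

    p_safe = np.clip(p, 1e-300, None)
    nll = -float(np.log(p_safe).sum())

    inv_p = 1.0 / np.clip(p, 1e-30, None)
    # C_ij = dt_i q_ij (G_i[r_j, s_j] - G_i[r_j, r_j]) / p_i
    C = (
        data.dt[:, None]
        * q
        * (G[:, _ROW_IDX, _COL_IDX] - G[:, _ROW_IDX, _ROW_IDX])
        * inv_p[:, None]
    )
    grad_theta = -C.sum(axis=0)
    grad_beta = -(data.Z * C.sum(axis=1)[:, None]).sum(axis=0) if len(beta) else np.zeros(0)
    return nll, np.concatenate([grad_theta, grad_beta])


def _pack(model: CovariateModel) -> np.ndarray:
    return np.concatenate([model.theta, model.beta])


def log_likelihood(model: CovariateModel, cohort: Cohort) -> float:
    """Panel log-likelihood of the cohort under ``model``.

    Sums log interval transition probabilities over consecutive visit
    pairs, conditioning on each patient's first observed state.
    """
    data = build_interval_data(cohort, model.covariates, model.centering)
    logs = _interval_log_probs(_pack(model), data)
    if np.any(logs <= np.log(1e-300) + 1.0):
        bad = int(np.argmin(logs))
        raise RegressionError(
            f"interval with zero transition probability (state {data.s0[bad]} -> "
            f"{data.s1[bad]} over {data.dt[bad]:g} years)"
        )
    return float(logs.sum())


def crude_rates(data: IntervalData, floor: float = 1e-3) -> np.ndarray:
    """Observed direct transition counts over total time at risk, floored.

    Initializer for the optimizer: multi-stage observed jumps count as
    direct transitions, exposure is total interval time spent starting
    in each state.
    """
    counts = np.zeros(N_TRANS)
    exposure = np.zeros(N_TRANS)
    for j, (r, s) in enumerate(TRANSITIONS):
        in_r = data.s0 == r
        exposure[j] = data.dt[in_r].sum()
        counts[j] = np.sum(in_r & (data.s1 == s))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(exposure > 0, counts / np.where(exposure > 0, exposure, 1.0), 0.0)
    return np.maximum(q, floor)


@dataclass
class FitResult:
    """Converged model plus inference byproducts."""

    model: CovariateModel
    loglik: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int
    grad_norm: float
    message: str = ""
    cov: np.ndarray | None = None
    n_patients: int = 0
    n_intervals: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        return _pack(self.model)

    def beta_se(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("fit has no covariance matrix")
        return np.sqrt(np.diag(self.cov)[N_TRANS:])

    def to_json(self, path=None) -> str:
        extra = {
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_patients": self.n_patients,
            "n_intervals": self.n_intervals,
        }
        if self.cov is not None:
            extra["covariance"] = self.cov.tolist()
        return self.model.to_json(path, extra=extra)


def hazard_ratio_table(fit: FitResult) -> pd.DataFrame:
    """Per-covariate hazard ratios with Wald 95% CIs and two-sided p-values."""
    se = fit.beta_se()
    beta = fit.model.beta
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = np.where(se > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return pd.DataFrame(
        {
            "covariate": list(fit.model.covariates),
            "hazard_ratio": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p_value": p,
        }
    )


def format_hr_row(hr: float, lo: float, hi: float) -> str:
    """Format a hazard ratio row as e.g. ``"1.31 (0.969–1.767)"``."""
    return f"{hr:.2f} ({lo:.3f}–{hi:.3f})"


def fit(
    cohort: Cohort,
    covariates: Sequence[str] = (),
    init: CovariateModel | None = None,
    centering: Mapping[str, float] | None = None,
    max_iter: int = 1000,
    compute_cov: bool = True,
    horizon: float = 20.0,
) -> FitResult:
    """Maximize the panel likelihood over log intensities and covariate effects.

    Baseline log intensities start from crude observed rates (counts
    over time at risk, floored at 1e-3 for unobserved transitions) and
    covariate coefficients from zero, unless ``init`` provides a model.
    Bounds keep intensities positive and finite; a coefficient pinned
    at a bound triggers a boundary warning.
    """
    covariates = tuple(covariates)
    if init is not None and centering is None:
        centering = init.centering
    data = build_interval_data(cohort, covariates, centering)

    if init is not None:
        if tuple(init.covariates) != covariates:
            raise ValueError("init model covariates must match requested covariates")
        x0 = _pack(init)
    else:
        x0 = np.concatenate([np.log(crude_rates(data)), np.zeros(len(covariates))])
    x0 = np.clip(
        x0,
        [THETA_BOUNDS[0]] * N_TRANS + [BETA_BOUNDS[0]] * len(covariates),
        [THETA_BOUNDS[1]] * N_TRANS + [BETA_BOUNDS[1]] * len(covariates),
    )
    bounds = [THETA_BOUNDS] * N_TRANS + [BETA_BOUNDS] * len(covariates)

    res = optimize.minimize(
        _negloglik_grad,
        x0,
        args=(data,),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-9, "gtol": 1e-6, "maxfun": 10**6},
    )
    if not res.success and "ITERATIONS REACHED LIMIT" in str(res.message):
        raise FitError(
            f"no convergence after {max_iter} iterations: {res.message} "
            f"(nll={res.fun:.6g}, |grad|={np.max(np.abs(res.jac)):.3g})"
        )

    fit_warnings = []
    if not res.success:
        msg = f"optimizer stopped early: {res.message}"
        warnings.warn(msg)
        fit_warnings.append(msg)
    at_bound = np.flatnonzero(np.abs(res.x[:N_TRANS] - THETA_BOUNDS[0]) < 1e-6)
    if len(at_bound):
        names = [f"q{TRANSITIONS[j][0]}{TRANSITIONS[j][1]}" for j in at_bound]
        msg = (
            f"baseline intensities at the lower bound (no information in data): {names}"
        )
        warnings.warn(msg)
        fit_warnings.append(msg)

    model = CovariateModel(
        theta=res.x[:N_TRANS],
        beta=res.x[N_TRANS:],
        covariates=covariates,
        centering=data.centering,
        horizon=horizon,
    )
    n_params = N_TRANS + len(covariates)
    result = FitResult(
        model=model,
        loglik=-float(res.fun),
        aic=2.0 * float(res.fun) + 2.0 * n_params,
        n_params=n_params,
        converged=bool(res.success),
        n_iter=int(res.nit),
        grad_norm=float(np.max(np.abs(res.jac))),
        message=str(res.message),
        n_patients=data.n_patients,
        n_intervals=data.n_intervals,
        warnings=fit_warnings,
    )
    if compute_cov:
        result.cov = _covariance(res.x, data, result)
    return result


def _covariance(x: np.ndarray, data: IntervalData, result: FitResult) -> np.ndarray | None:
    try:
        H = approx_hess1(x, _negloglik, args=(data,))
        H = (H + H.T) / 2.0
        eigvals = np.linalg.eigvalsh(H)
        if eigvals.min() <= 0:
            raise np.linalg.LinAlgError("Hessian not positive definite")
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as err:
        msg = f"covariance unavailable ({err}); confidence intervals disabled"
        warnings.warn(msg)
        result.warnings.append(msg)
        return None
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _warn_duplicate_columns(data: IntervalData) -> list[str]:
    dup = []
    k = len(data.covariates)
    for i in range(k):
        for j in range(i + 1, k):
            if np.allclose(data.Z[:, i], data.Z[:, j]):
                dup.append(data.covariates[j])
                warnings.warn(
                    f"covariates {data.covariates[i]!r} and {data.covariates[j]!r} are "
                    "identical; backward elimination will drop one"
                )
    return dup


def backward_eliminate(
    cohort: Cohort,
    covariates: Sequence[str],
    centering: Mapping[str, float] | None = None,
    **fit_kwargs,
) -> tuple[FitResult, list[tuple[str, float]]]:
    """AIC backward elimination with full refits at every step.

    Repeatedly drops the single covariate whose removal gives the
    lowest AIC, as long as that AIC improves on the current model's;
    ties within 1e-6 drop the covariate later in the supplied order.
    Retained covariates may well have p >= 0.05 - the criterion is AIC,
    not significance.  Returns the final fit and the ordered trace of
    (dropped covariate, AIC after dropping).
    """
    covariates = list(covariates)
    trace: list[tuple[str, float]] = []
    if centering is None:
        centering = default_centering(cohort, covariates)
    if covariates:
        _warn_duplicate_columns(build_interval_data(cohort, covariates, centering))
    try:
        current = fit(cohort, covariates, centering=centering, **fit_kwargs)
    except FitError as err:
        raise FitError(f"full model fit failed: {err}", trace=trace) from err

    while covariates:
        candidates = []
        for name in covariates:
            reduced = [c for c in covariates if c != name]
            keep = [i for i, c in enumerate(covariates) if c != name]
            warm = CovariateModel(
                theta=current.model.theta,
                beta=current.model.beta[keep],
                covariates=tuple(reduced),
                centering={c: centering.get(c, 0.0) for c in reduced},
            )
            try:
                cand = fit(cohort, reduced, init=warm, centering=centering, **fit_kwargs)
            except FitError as err:
                raise FitError(
                    f"fit without {name!r} failed: {err}", trace=trace
                ) from err
            candidates.append((name, cand))
        best_name, best = candidates[0]
        for name, cand in candidates[1:]:
            if cand.aic < best.aic - 1e-6:
                best_name, best = name, cand
            elif abs(cand.aic - best.aic) <= 1e-6:
                best_name, best = name, cand  # tie: drop the later covariate
        if best.aic < current.aic:
            covariates = [c for c in covariates if c != best_name]
            trace.append((best_name, best.aic))
            current = best
        else:
            break
    return current, trace


# ---------------------------------------------------------------------------
# Parametric bootstrap for derived probabilities
# ---------------------------------------------------------------------------

def bootstrap_probability_ci(
    fit_result: FitResult,
    schedule: CovariateSchedule,
    from_state: int,
    t0: float = 0.0,
    window: float = 1.0,
    draws: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Point estimate and percentile 95% CI for a PDR progression probability.

    Samples parameter vectors from the asymptotic normal at the MLE,
    recomputes the queried probability per draw, and returns the
    2.5th/97.5th percentiles.  Deterministic given ``seed``.
    """
    if fit_result.cov is None:
        raise ValueError("fit has no covariance; bootstrap CI unavailable")
    if draws < 1:
        raise ValueError("draws must be >= 1")
    model = fit_result.model
    point = pdr_probability(model, schedule, from_state, t0=t0, window=window)

    rng = np.random.default_rng(seed)
    mean = fit_result.params
    w, V = np.linalg.eigh(fit_result.cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    samples = mean[None, :] + rng.standard_normal((draws, len(mean))) @ L.T
    vals = np.empty(draws)
    for i, x in enumerate(samples):
        m = dataclasses.replace(model, theta=x[:N_TRANS], beta=x[N_TRANS:])
        vals[i] = pdr_probability(m, schedule, from_state, t0=t0, window=window)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return point, float(lo), float(hi)
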