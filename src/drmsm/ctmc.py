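"""Deterministic CTMC machinery for progressive 5-state disease models.

The chain has states 1 (no retinopathy), 2 (mild NPDR), 3 (moderate
NPDR), 4 (severe NPDR) and 5 (PDR, absorbing).  Progression is
irreversible and may skip stages, so the generator is strictly upper
triangular with all ten forward transitions allowed.  Covariates act
proportionally on every transition intensity with a single shared
coefficient per covariate:

    q_rs(z) = exp(theta_rs + sum_k beta_k * (z_k - c_k)),   r < s <= 5

where ``c_k`` are stored centering constants, so ``exp(theta_rs)`` is
the intensity for a patient at the reference covariate values and
``exp(beta_k)`` is the hazard ratio per unit of covariate k, identical
for every transition.

Time-dependent covariates are piecewise constant between visits
(:class:`CovariateSchedule`), which makes every inter-visit segment a
homogeneous chain: transition probabilities over an interval are
products of segment matrix exponentials, and sojourn times integrate
the piecewise-exponential survival in closed form per segment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm as _scipy_expm

from ._expm import expm_batch

N_STATES = 5

#: The ten allowed transitions (from, to), 1-based, row-major.
TRANSITIONS: tuple[tuple[int, int], ...] = tuple(
    (r, s) for r in range(1, N_STATES) for s in range(r + 1, N_STATES + 1)
)

STATE_NAMES = {
    1: "no retinopathy",
    2: "mild NPDR",
    3: "moderate NPDR",
    4: "severe NPDR",
    5: "PDR",
}

_ROW_IDX = np.array([r - 1 for r, _ in TRANSITIONS])
_COL_IDX = np.array([s - 1 for _, s in TRANSITIONS])


class ScheduleError(ValueError):
    """A covariate schedule does not cover the requested interval."""


@dataclass(frozen=True)
class CovariateModel:
    """Proportional-intensity model for the progressive 5-state chain.

    Parameters
    ----------
    theta : array, shape (10,)
        Log intensities of the ten forward transitions at the
        reference (centered) covariate values, ordered as
        :data:`TRANSITIONS`.
    beta : array, shape (k,)
        Shared log hazard ratios, one per covariate.
    covariates : sequence of str
        Covariate names, aligned with ``beta``.
    centering : mapping of str to float
        Centering constant per covariate (0 for indicators).
    horizon : float
        Default integration horizon in years for sojourn times.
    """

    theta: np.ndarray
    beta: np.ndarray
    covariates: tuple[str, ...] = ()
    centering: Mapping[str, float] = field(default_factory=dict)
    horizon: float = 20.0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        beta = np.asarray(self.beta, dtype=float)
        if theta.shape != (len(TRANSITIONS),):
            raise ValueError(f"theta must have shape (10,), got {theta.shape}")
        covs = tuple(self.covariates)
        if beta.shape != (len(covs),):
            raise ValueError("beta length must match number of covariates")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "covariates", covs)
        object.__setattr__(
            self, "centering", {c: float(self.centering.get(c, 0.0)) for c in covs}
        )

    # -- covariate handling -------------------------------------------------
    def covariate_array(self, z: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Original-scale covariate vector ordered like ``self.covariates``."""
        if isinstance(z, Mapping):
            missing = [c for c in self.covariates if c not in z]
            if missing:
                raise ValueError(f"missing covariate values: {missing}")
            arr = np.array([float(z[c]) for c in self.covariates])
        else:
            arr = np.asarray(z, dtype=float)
            if arr.shape != (len(self.covariates),):
                raise ValueError(
                    f"expected {len(self.covariates)} covariate values, got {arr.shape}"
                )
        return arr

    def center(self, Z: np.ndarray) -> np.ndarray:
        offsets = np.array([self.centering[c] for c in self.covariates])
        return np.asarray(Z, dtype=float) - offsets

    # -- intensities --------------------------------------------------------
    def rates(self, z: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Transition intensities q_rs(z), shape (10,), z on original scale."""
        zc = self.center(self.covariate_array(z))
        return np.exp(self.theta + zc @ self.beta)

    def rates_batch(self, Z_centered: np.ndarray) -> np.ndarray:
        """Intensities for pre-centered covariate rows, shape (m, 10)."""
        Z_centered = np.atleast_2d(np.asarray(Z_centered, dtype=float))
        lp = Z_centered @ self.beta if len(self.covariates) else np.zeros(len(Z_centered))
        return np.exp(self.theta[None, :] + lp[:, None])

    def generator(self, z: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        return generator_from_rates(self.rates(z))

    def generator_batch(self, Z_centered: np.ndarray) -> np.ndarray:
        return generator_from_rates(self.rates_batch(Z_centered))

    def hazard_ratios(self) -> dict[str, float]:
        return {c: float(np.exp(b)) for c, b in zip(self.covariates, self.beta)}

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "states": [STATE_NAMES[i] for i in range(1, N_STATES + 1)],
            "transitions": [list(t) for t in TRANSITIONS],
            "theta": self.theta.tolist(),
            "beta": self.beta.tolist(),
            "covariates": list(self.covariates),
            "centering": dict(self.centering),
            "horizon": self.horizon,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateModel":
        return cls(
            theta=np.asarray(d["theta"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
            covariates=tuple(d.get("covariates", ())),
            centering=dict(d.get("centering", {})),
            horizon=float(d.get("horizon", 20.0)),
        )

    def to_json(self, path=None, extra: Mapping | None = None) -> str:
        doc = self.to_dict()
        if extra:
            doc.update(extra)
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CovariateModel":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        return cls.from_dict(doc)


def homogeneous_model(
    rates: Mapping[tuple[int, int], float], horizon: float = 20.0
) -> CovariateModel:
    """Covariate-free model from a dict of per-transition intensities.

    Transitions absent from ``rates`` get a numerically-zero intensity
    (exactly-zero rows are representable only in generator form; a log
    intensity of -40 is zero to double precision on any relevant
    horizon).
    """
    theta = np.full(len(TRANSITIONS), -40.0)
    for (r, s), q in rates.items():
        if (r, s) not in TRANSITIONS:
            raise ValueError(f"not a forward transition: {(r, s)}")
        theta[TRANSITIONS.index((r, s))] = np.log(q) if q > 0 else -40.0
    return CovariateModel(theta=theta, beta=np.zeros(0), horizon=horizon)


def generator_from_rates(q: np.ndarray) -> np.ndarray:
    """Assemble generator matrices from transition-intensity vectors.

    Parameters
    ----------
    q : array, shape (..., 10)
        Intensities ordered as :data:`TRANSITIONS`.

    Returns
    -------
    ndarray, shape (..., 5, 5)
        Upper-triangular generators; each row sums to zero and the
        absorbing PDR row is identically zero.
    """
    q = np.asarray(q, dtype=float)
    Q = np.zeros(q.shape[:-1] + (N_STATES, N_STATES))
    Q[..., _ROW_IDX, _COL_IDX] = q
    d = np.arange(N_STATES)
    Q[..., d, d] = -Q.sum(axis=-1)
    return Q


def build_generator(
    model: CovariateModel, z: Mapping[str, float] | Sequence[float]
) -> np.ndarray:
    """Generator matrix Q(z) for one covariate vector on the original scale."""
    return model.generator(z)


def _clean_probability(P: np.ndarray) -> np.ndarray:
    # Clip roundoff: exact zeros below the diagonal, tiny negatives to 0.
    P = np.where(P < 0, 0.0, P)
    il = np.tril_indices(N_STATES, k=-1)
    P[..., il[0], il[1]] = 0.0
    np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_matrix(Q: np.ndarray, dt: float) -> np.ndarray:
    """Transition probability matrix P = expm(Q*dt) for one generator."""
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (N_STATES, N_STATES):
        raise ValueError(f"expected a {N_STATES}x{N_STATES} generator, got {Q.shape}")
    if dt == 0:
        return np.eye(N_STATES)
    return _clean_probability(_scipy_expm(Q * dt))


@dataclass(frozen=True)
class CovariateSchedule:
    """Piecewise-constant covariate path over half-open segments.

    ``breakpoints`` has m+1 increasing times; segment j is
    [breakpoints[j], breakpoints[j+1]) and carries row j of ``values``
    (original scale).  After the last observation the final covariate
    vector is carried forward to any requested horizon via
    :meth:`extended`.
    """

    breakpoints: np.ndarray
    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != len(self.names):
            vals = vals.reshape(-1, len(self.names))
        if len(bp) != len(vals) + 1:
            raise ValueError("need one more breakpoint than segment rows")
        if len(bp) >= 2 and not np.all(np.diff(bp) > 0):
            raise ScheduleError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))

    @classmethod
    def from_visits(
        cls, times: Sequence[float], Z: np.ndarray, names: Iterable[str]
    ) -> "CovariateSchedule":
        """Segments [t_j, t_{j+1}) carrying the covariates observed at t_j."""
        times = np.asarray(times, dtype=float)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if len(times) != len(Z):
            raise ValueError("one covariate row per visit time required")
        if len(np.unique(times)) != len(times):
            raise ScheduleError("duplicate visit times")
        return cls(breakpoints=times, values=Z[:-1], names=tuple(names))

    @property
    def start(self) -> float:
        return float(self.breakpoints[0])

    @property
    def end(self) -> float:
        return float(self.breakpoints[-1])

    @property
    def n_segments(self) -> int:
        return len(self.values)

    def is_empty(self) -> bool:
        return self.n_segments == 0

    def extended(self, horizon: float) -> "CovariateSchedule":
        """Carry the last observed covariate vector forward to ``horizon``."""
        if self.is_empty():
            raise ScheduleError("cannot extend an empty (single-visit) schedule")
        if horizon <= self.end:
            return self
        return CovariateSchedule(
            breakpoints=np.append(self.breakpoints, horizon),
            values=np.vstack([self.values, self.values[-1]]),
            names=self.names,
        )

    def segments(self, t1: float, tn: float) -> tuple[np.ndarray, np.ndarray]:
        """Durations and covariate rows of segments intersecting [t1, tn]."""
        if tn < t1:
            raise ValueError("tn must be >= t1")
        eps = 1e-9
        if t1 < self.start - eps or tn > self.end + eps:
            raise ScheduleError(
                f"schedule covers [{self.start}, {self.end}], requested [{t1}, {tn}]"
            )
        lo = np.clip(self.breakpoints[:-1], t1, tn)
        hi = np.clip(self.breakpoints[1:], t1, tn)
        dt = hi - lo
        keep = dt > 0
        return dt[keep], self.values[keep]

    def with_shift(self, name: str, delta: float) -> "CovariateSchedule":
        """Schedule with covariate ``name`` shifted by ``delta`` everywhere."""
        if name not in self.names:
            raise ValueError(f"unknown covariate {name!r}")
        vals = self.values.copy()
        vals[:, self.names.index(name)] += delta
        return dataclasses.replace(self, values=vals)

    def with_overrides(self, overrides: Mapping[str, float]) -> "CovariateSchedule":
        """Schedule with named covariates forced to constant values."""
        vals = self.values.copy()
        for name, value in overrides.items():
            if name not in self.names:
                raise ValueError(f"unknown covariate {name!r}")
            vals[:, self.names.index(name)] = value
        return dataclasses.replace(self, values=vals)


def _model_segments(
    model: CovariateModel, schedule: CovariateSchedule, t1: float, tn: float
) -> tuple[np.ndarray, np.ndarray]:
    """Segment durations and centered model-covariate rows covering [t1, tn]."""
    sched = schedule.extended(tn) if tn > schedule.end else schedule
    dt, Z = sched.segments(t1, tn)
    if len(model.covariates):
        idx = []
        for c in model.covariates:
            if c not in sched.names:
                raise ScheduleError(f"schedule lacks model covariate {c!r}")
            idx.append(sched.names.index(c))
        Zc = model.center(Z[:, idx])
    else:
        Zc = np.zeros((len(dt), 0))
    return dt, Zc


def interval_probability(
    model: CovariateModel, schedule: CovariateSchedule, t1: float, tn: float
) -> np.ndarray:
    """Transition probabilities over [t1, tn] as a product of homogeneous segments."""
    if tn < t1:
        raise ValueError("tn must be >= t1")
    if tn == t1:
        return np.eye(N_STATES)
    dt, Zc = _model_segments(model, schedule, t1, tn)
    Q = model.generator_batch(Zc)
    P_seg = expm_batch(Q * dt[:, None, None])
    P = P_seg[0]
    for k in range(1, len(P_seg)):
        P = P @ P_seg[k]
    return _clean_probability(P)


def _segment_exit_rates(
    model: CovariateModel, Zc: np.ndarray, state: int
) -> np.ndarray:
    rates = model.rates_batch(Zc)
    cols = [j for j, (r, _) in enumerate(TRANSITIONS) if r == state]
    return rates[:, cols].sum(axis=1)


def sojourn_time(
    model: CovariateModel,
    schedule: CovariateSchedule,
    state: int,
    t0: float = 0.0,
    horizon: float | None = None,
    return_diagnostics: bool = False,
):
    """Expected years spent in ``state`` from ``t0``, truncated at ``horizon``.

    Integrates the survival of the state's exit hazard, which is
    piecewise constant under the covariate schedule: with segment exit
    rates lambda_k over lengths Delta_k,

        S = sum_k [prod_{j<k} exp(-lambda_j Delta_j)]
                  * (1 - exp(-lambda_k Delta_k)) / lambda_k,

    with the limit Delta_k as lambda_k -> 0 (Taylor expansion below
    lambda_k * Delta_k < 1e-8).
    """
    if state not in (1, 2, 3, 4):
        raise ValueError("sojourn time is defined for the transient states 1-4")
    horizon = model.horizon if horizon is None else float(horizon)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    dt, Zc = _model_segments(model, schedule, t0, t0 + horizon)
    lam = _segment_exit_rates(model, Zc, state)
    x = lam * dt
    surv_before = np.exp(-np.concatenate([[0.0], np.cumsum(x)[:-1]]))
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            x < 1e-8, dt - lam * dt**2 / 2.0, (1.0 - np.exp(-x)) / np.where(lam > 0, lam, 1.0)
        )
    S = float(np.sum(surv_before * contrib))
    if not return_diagnostics:
        return S
    surv_end = float(np.exp(-np.sum(x)))
    lam_last = float(lam[-1]) if len(lam) else 0.0
    tail = surv_end / lam_last if lam_last > 0 else np.inf
    return S, {"survival_at_horizon": surv_end, "tail_bound": tail}


def sojourn_reduction(
    model: CovariateModel,
    schedule: CovariateSchedule,
    state: int,
    covariate: str,
    delta: float = 1.0,
    t0: float = 0.0,
    horizon: float | None = None,
) -> tuple[float, float]:
    """Percent and absolute sojourn-time reduction for a covariate shift.

    Recomputes the sojourn time with ``covariate`` shifted by ``delta``
    on every segment and returns ``((1 - S_shifted/S) * 100, S - S_shifted)``.
    """
    if covariate not in model.covariates:
        raise ValueError(f"covariate {covariate!r} not in model")
    base = sojourn_time(model, schedule, state, t0=t0, horizon=horizon)
    shifted = sojourn_time(
        model, schedule.with_shift(covariate, delta), state, t0=t0, horizon=horizon
    )
    return (1.0 - shifted / base) * 100.0, base - shifted


def pdr_probability(
    model: CovariateModel,
    schedule: CovariateSchedule,
    from_state: int,
    t0: float = 0.0,
    window: float = 1.0,
) -> float:
    """Probability of reaching PDR within ``window`` years starting in ``from_state``."""
    if not 1 <= from_state <= 4:
        raise ValueError("from_state must be a transient state 1-4")
    if window < 0:
        raise ValueError("window must be >= 0")
    P = interval_probability(model, schedule, t0, t0 + window)
    return float(P[from_state - 1, N_STATES - 1])


def time_average_rate_matrix(
    model: CovariateModel,
    schedules: Sequence[CovariateSchedule],
    overrides: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Across-patient mean and SD of time-averaged transition intensities.

    For each patient the length-weighted average of q_rs(t) over the
    observed follow-up (no horizon extension) is computed, optionally
    with covariates forced to fixed values (e.g. the ethnicity
    indicator set to non-Hispanic and time-independent covariates to
    their means).  The dispersion is the across-patient standard
    deviation of these per-patient averages.
    """
    per_patient = []
    for sched in schedules:
        if sched.is_empty():
            continue
        if overrides:
            sched = sched.with_overrides(overrides)
        dt, Zc = _model_segments(model, sched, sched.start, sched.end)
        q = model.rates_batch(Zc)
        qbar = (dt[:, None] * q).sum(axis=0) / dt.sum()
        per_patient.append(generator_from_rates(qbar))
    if not per_patient:
        raise ValueError("no informative schedules (all empty)")
    stack = np.array(per_patient)
    sd = stack.std(axis=0, ddof=1) if len(stack) > 1 else np.zeros_like(stack[0])
    return stack.mean(axis=0), sd
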