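"""Synthetic panel-observed cohorts with the structure the analysis assumes.

The generator emulates a safety-net retinopathy cohort: ~230 patients,
baseline stage mix 28.3/31.7/26.1/13.9% over states 1-4, age ~
N(56, 10), 68.7% Hispanic, 62.2% female, diabetes duration ~
N(13.1, 7.5) truncated at 0.8 years, baseline HbA1c ~ N(9.7, 2.4)
truncated to (5.4, 16.8) with a declining trend over follow-up,
annual visits with jitter over 2-10 years of follow-up, latent
trajectories from the progressive 5-state CTMC, panel observation at
visit times, and completely-at-random missingness in HbA1c and
diabetes duration.

True baseline intensities default to the fitted non-Hispanic
at-mean-covariates rates of the study (q12 = 0.209, q23 = 0.142,
q34 = 0.097, q45 = 0.172, plus the skip transitions) and true hazard
ratios to age 0.99/yr, DM duration 1.02/yr, Hispanic 1.31.  The HbA1c
hazard ratio is never reported by the study; the default 1.10 per
percentage point is an assumption (bracketed from the published
sojourn-vs-HbA1c curve) and is flagged as such in the truth record.

Trajectory simulation uses competing exponentials within each
constant-covariate segment, which is exact in distribution for
piecewise-constant intensities and fully independent of the analytic
matrix-exponential engine - the two act as cross-checks.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cohort import Cohort, PatientSeries, VisitRecord, _flag_eligibility
from .ctmc import TRANSITIONS, CovariateModel, CovariateSchedule, homogeneous_model

#: Fitted at-mean-covariates intensities used as the generating truth.
DEFAULT_BASELINE_RATES: dict[tuple[int, int], float] = {
    (1, 2): 0.209,
    (1, 3): 0.068,
    (1, 4): 0.003,
    (1, 5): 0.0004,
    (2, 3): 0.142,
    (2, 4): 0.013,
    (2, 5): 0.027,
    (3, 4): 0.097,
    (3, 5): 0.034,
    (4, 5): 0.172,
}

DEFAULT_HAZARD_RATIOS: dict[str, float] = {
    "age": 0.99,
    "dm_duration": 1.02,
    "hispanic": 1.31,
    "hba1c": 1.10,  # assumption: never reported by the study
}


@dataclass
class SimConfig:
    """Generating conditions for a synthetic cohort; the seed is mandatory."""

    seed: int
    n_patients: int = 230
    stage_probs: tuple[float, ...] = (0.283, 0.317, 0.261, 0.139)

    age_mean: float = 56.0
    age_sd: float = 10.0
    p_hispanic: float = 0.687
    p_female: float = 0.622
    p_hypertension: float = 0.804
    p_dyslipidemia: float = 0.748
    p_ckd: float = 0.086
    p_mi: float = 0.022
    p_cva: float = 0.035
    dm_mean: float = 13.1
    dm_sd: float = 7.5
    dm_min: float = 0.8
    hba1c_mean: float = 9.7
    hba1c_sd: float = 2.4
    hba1c_baseline_range: tuple[float, float] = (5.4, 16.8)
    hba1c_drift: float = -0.15    # % per year, reproduces the cohort-level decline
    hba1c_noise: float = 0.8
    hba1c_bounds: tuple[float, float] = (4.0, 20.0)
    sbp_mean: float = 135.6
    sbp_sd: float = 18.2
    dbp_mean: float = 76.3
    dbp_sd: float = 11.5
    bp_visit_sd: float = 5.0
    anti_vegf_rate: float = 0.3   # mean injections per year (inert by default)

    baseline_rates: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RATES))
    hazard_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS))

    follow_up: tuple[float, float] = (2.0, 10.0)   # uniform range (equal = fixed)
    visit_jitter: float = 0.2
    hba1c_missing_rate: float = 0.15   # per visit
    dm_missing_rate: float = 0.10      # per patient

    def __post_init__(self) -> None:
        probs = np.asarray(self.stage_probs, dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("stage_probs must be probabilities summing to 1")
        if any(q < 0 for q in self.baseline_rates.values()):
            raise ValueError("intensities must be >= 0")
        for name in ("hba1c_missing_rate", "dm_missing_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {r}")

    def reference_covariates(self) -> dict[str, float]:
        """Covariate values at which the baseline intensities apply."""
        ref = {"age": self.age_mean, "dm_duration": self.dm_mean, "hba1c": self.hba1c_mean}
        return {
            name: ref.get(name, 0.0) for name in self.hazard_ratios
        }

    def true_model(self) -> CovariateModel:
        """The generating CovariateModel (intensities referenced to the means)."""
        base = homogeneous_model(self.baseline_rates)
        names = tuple(self.hazard_ratios)
        return CovariateModel(
            theta=base.theta,
            beta=np.log([self.hazard_ratios[c] for c in names]),
            covariates=names,
            centering=self.reference_covariates(),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline_rates"] = {f"{r}->{s}": q for (r, s), q in self.baseline_rates.items()}
        return d

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        """Build from a YAML file path or open stream."""
        doc = yaml.safe_load(source.read() if hasattr(source, "read") else open(source).read())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SimConfig":
        doc = dict(doc)
        if "baseline_rates" in doc:
            doc["baseline_rates"] = {
                tuple(int(x) for x in key.replace("->", " ").split()): float(q)
                for key, q in doc["baseline_rates"].items()
            }
        for key in ("stage_probs", "follow_up", "hba1c_baseline_range", "hba1c_bounds"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class Trajectory:
    """Latent continuous-time path: initial state plus (jump time, new state) pairs."""

    initial_state: int
    jump_times: list[float]
    jump_states: list[int]
    schedule: CovariateSchedule

    def state_at(self, t: float) -> int:
        state = self.initial_state
        for tj, sj in zip(self.jump_times, self.jump_states):
            if tj <= t:
                state = sj
            else:
                break
        return state


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    # Resampling is exact and cheap at these mild truncations.
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = (out < lo) | (out > hi)
    return out


def simulate_covariates(
    config: SimConfig, rng: np.random.Generator, n: int | None = None, max_years: int = 10
):
    """Baseline covariate draws plus yearly HbA1c paths.

    Returns ``(baseline, hba1c_path)`` where ``baseline`` is a dict of
    arrays over patients and ``hba1c_path`` has shape
    ``(n, max_years + 1)`` with the value for year y equal to
    baseline + drift*y + noise, truncated to the configured bounds.
    """
    n = config.n_patients if n is None else n
    baseline = {
        "age": rng.normal(config.age_mean, config.age_sd, n),
        "hispanic": (rng.random(n) < config.p_hispanic).astype(float),
        "female": (rng.random(n) < config.p_female).astype(float),
        "hypertension": (rng.random(n) < config.p_hypertension).astype(float),
        "dyslipidemia": (rng.random(n) < config.p_dyslipidemia).astype(float),
        "ckd": (rng.random(n) < config.p_ckd).astype(float),
        "mi": (rng.random(n) < config.p_mi).astype(float),
        "cva": (rng.random(n) < config.p_cva).astype(float),
        "dm_duration": _truncated_normal(rng, config.dm_mean, config.dm_sd, config.dm_min, np.inf, n),
        "hba1c0": _truncated_normal(
            rng, config.hba1c_mean, config.hba1c_sd, *config.hba1c_baseline_range, size=n
        ),
        "sbp": rng.normal(config.sbp_mean, config.sbp_sd, n),
    }
    baseline["dbp"] = np.minimum(
        rng.normal(config.dbp_mean, config.dbp_sd, n), baseline["sbp"] - 5.0
    )
    years = np.arange(max_years + 1)
    path = (
        baseline["hba1c0"][:, None]
        + config.hba1c_drift * years[None, :]
        + rng.normal(0.0, config.hba1c_noise, (n, max_years + 1))
    )
    path[:, 0] = baseline["hba1c0"]  # the baseline visit reports the baseline lab
    path = np.clip(path, *config.hba1c_bounds)
    return baseline, path


def simulate_trajectory(
    model: CovariateModel,
    schedule: CovariateSchedule,
    initial_state: int,
    rng: np.random.Generator,
) -> Trajectory:
    """Simulate one latent path by competing exponentials per segment.

    Within each constant-covariate segment the holding time in state r
    is Exponential(sum_s q_rs); on a jump the destination is chosen
    with probability q_rs / sum q_r.  Unelapsed holding times are
    redrawn at segment boundaries, which is valid by memorylessness.
    """
    if not 1 <= initial_state <= 5:
        raise ValueError("initial_state must be in 1..5")
    jump_times: list[float] = []
    jump_states: list[int] = []
    state = initial_state
    for k in range(schedule.n_segments):
        if state == 5:
            break
        t = float(schedule.breakpoints[k])
        t_end = float(schedule.breakpoints[k + 1])
        z = dict(zip(schedule.names, schedule.values[k]))
        rates = {
            s: q
            for (r, s), q in zip(TRANSITIONS, model.rates(
                {c: z[c] for c in model.covariates} if model.covariates else {}
            ))
            if r == state and q > 0
        }
        while t < t_end and state != 5:
            total = sum(rates.values())
            if total <= 0:
                break
            t = t + rng.exponential(1.0 / total)
            if t >= t_end:
                break
            dests = list(rates)
            probs = np.array([rates[s] for s in dests]) / total
            state = int(rng.choice(dests, p=probs))
            jump_times.append(t)
            jump_states.append(state)
            rates = {
                s: q
                for (r, s), q in zip(TRANSITIONS, model.rates(
                    {c: z[c] for c in model.covariates} if model.covariates else {}
                ))
                if r == state and q > 0
            }
    return Trajectory(initial_state, jump_times, jump_states, schedule)


def panel_observe(
    traj: Trajectory,
    visit_times: Sequence[float],
    patient_id: str = "p0",
    baseline: Mapping[str, float] | None = None,
    visit_covariates: Mapping[str, Sequence[float]] | None = None,
) -> PatientSeries:
    """Observe the latent trajectory only at clinic visits.

    The stage at each visit is the latent state at that time; latent
    jump times are discarded.  Panel observation is what produces
    apparent multi-stage jumps between consecutive visits.
    """
    visit_times = list(visit_times)
    if visit_times != sorted(visit_times) or visit_times[0] != 0:
        raise ValueError("visit times must be sorted with the first at 0")
    baseline = dict(baseline or {})
    vc = {k: list(v) for k, v in (visit_covariates or {}).items()}
    visits = []
    for j, t in enumerate(visit_times):
        visits.append(
            VisitRecord(
                t=float(t),
                stage=traj.state_at(t),
                **{
                    name: float(vc[name][j]) if name in vc else math.nan
                    for name in ("hba1c", "sbp", "dbp", "anti_vegf_count", "bcva_logmar")
                },
            )
        )
    return PatientSeries(
        patient_id=patient_id,
        visits=visits,
        age=baseline.get("age", math.nan),
        female=baseline.get("female", math.nan),
        hispanic=baseline.get("hispanic", math.nan),
        dm_duration=baseline.get("dm_duration", math.nan),
        hypertension=baseline.get("hypertension", math.nan),
        extras={
            k: baseline[k] for k in ("dyslipidemia", "ckd", "mi", "cva") if k in baseline
        },
    )


def inject_missingness(cohort: Cohort, config: SimConfig, rng: np.random.Generator) -> Cohort:
    """Delete HbA1c values (per visit) and DM durations (per patient) at random.

    Completely-at-random deletion at the configured rates; a patient
    never loses every HbA1c value (one survivor is kept so the LOCF /
    NOCB rules remain applicable).
    """
    patients = []
    for p in cohort.patients:
        visits = list(p.visits)
        drop = rng.random(len(visits)) < config.hba1c_missing_rate
        if drop.all() and len(visits):
            drop[rng.integers(len(visits))] = False
        visits = [
            dataclasses.replace(v, hba1c=math.nan) if d else v
            for v, d in zip(visits, drop)
        ]
        p = dataclasses.replace(p, visits=visits)
        if rng.random() < config.dm_missing_rate:
            p = dataclasses.replace(p, dm_duration=math.nan)
        patients.append(p)
    return dataclasses.replace(cohort, patients=patients)


def simulate_cohort(config: SimConfig) -> tuple[Cohort, dict]:
    """Full pipeline: covariates -> schedules -> trajectories -> panel -> missingness.

    Returns the observable cohort plus a truth record holding the
    generating parameters and the latent jump times, for test
    assertions.  Output is reproducible bit-for-bit for a given seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    model = config.true_model()
    max_years = int(math.ceil(config.follow_up[1])) + 1
    baseline, hba1c_path = simulate_covariates(config, rng, n, max_years=max_years)

    follow_up = rng.uniform(config.follow_up[0], config.follow_up[1], n)
    initial_states = rng.choice(
        np.arange(1, len(config.stage_probs) + 1), size=n, p=config.stage_probs
    )

    patients = []
    truth_patients = []
    sched_names = (
        "age",
        "dm_duration",
        "hispanic",
        "female",
        "hypertension",
        "hba1c",
        "sbp",
        "dbp",
        "anti_vegf_count",
    )
    for i in range(n):
        n_years = int(math.floor(follow_up[i]))
        times = [0.0]
        for j in range(1, n_years + 1):
            tj = j + rng.uniform(-config.visit_jitter, config.visit_jitter)
            if tj <= follow_up[i]:
                times.append(tj)
        m = len(times)
        hba1c = hba1c_path[i, :m]
        sbp = baseline["sbp"][i] + np.concatenate([[0.0], rng.normal(0, config.bp_visit_sd, m - 1)])
        dbp = np.minimum(
            baseline["dbp"][i] + np.concatenate([[0.0], rng.normal(0, config.bp_visit_sd, m - 1)]),
            sbp - 5.0,
        )
        anti_vegf = rng.poisson(config.anti_vegf_rate, m).astype(float)
        Z = np.column_stack(
            [
                np.full(m, baseline["age"][i]),
                np.full(m, baseline["dm_duration"][i]),
                np.full(m, baseline["hispanic"][i]),
                np.full(m, baseline["female"][i]),
                np.full(m, baseline["hypertension"][i]),
                hba1c,
                sbp,
                dbp,
                anti_vegf,
            ]
        )
        schedule = CovariateSchedule.from_visits(times, Z, sched_names)
        if schedule.is_empty():
            traj = Trajectory(int(initial_states[i]), [], [], schedule)
        else:
            traj = simulate_trajectory(model, schedule, int(initial_states[i]), rng)
        stages = [traj.state_at(t) for t in times]
        bcva = np.round(
            np.clip(0.1 * (np.array(stages) - 1) + rng.normal(0.25, 0.2, m), 0.0, 2.6), 2
        )
        series = panel_observe(
            traj,
            times,
            patient_id=f"p{i:04d}",
            baseline={
                k: baseline[k][i]
                for k in (
                    "age",
                    "female",
                    "hispanic",
                    "dm_duration",
                    "hypertension",
                    "dyslipidemia",
                    "ckd",
                    "mi",
                    "cva",
                )
            },
            visit_covariates={
                "hba1c": hba1c,
                "sbp": sbp,
                "dbp": dbp,
                "anti_vegf_count": anti_vegf,
                "bcva_logmar": bcva,
            },
        )
        _flag_eligibility(series)
        patients.append(series)
        truth_patients.append(
            {
                "patient_id": series.patient_id,
                "initial_state": int(initial_states[i]),
                "jump_times": list(traj.jump_times),
                "jump_states": list(traj.jump_states),
                "follow_up": float(follow_up[i]),
            }
        )

    cohort = Cohort(patients=patients)
    cohort = inject_missingness(cohort, config, rng)
    truth = {
        "config": config.to_dict(),
        "true_model": model.to_dict(),
        "hba1c_hr_is_assumption": True,
        "patients": truth_patients,
    }
    return cohort, truth
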