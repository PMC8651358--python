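"""Simulate-and-refit parameter recovery for the progression model.

The study's fitted quantities cannot be recomputed without its charts,
so the package validates itself by parameter recovery: cohorts are
simulated from the published final model (baseline intensities,
hazard ratios, covariate distributions), refit by panel maximum
likelihood, and the averaged estimates compared with the generating
values.  The same protocol backs the acceptance checks and the
selection-consistency experiment.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import inference
from .cohort import prepare_cohort
from .ctmc import TRANSITIONS
from .simulate import SimConfig, simulate_cohort

RECOVERY_COVARIATES = ("age", "dm_duration", "hispanic", "hba1c")


def recovery_config(seed: int, n_patients: int = 500, follow_up_years: float = 6.0) -> SimConfig:
    """Generating conditions for a recovery replicate.

    Annual jittered visits over a fixed follow-up; missingness is
    disabled so the experiment measures the estimator, not the
    imputation rules.
    """
    return SimConfig(
        seed=seed,
        n_patients=n_patients,
        follow_up=(follow_up_years, follow_up_years),
        hba1c_missing_rate=0.0,
        dm_missing_rate=0.0,
    )


def fit_one_replicate(
    config: SimConfig, covariates: Sequence[str] = RECOVERY_COVARIATES
) -> tuple[inference.FitResult, SimConfig]:
    """Simulate one cohort from ``config`` and refit it by panel MLE."""
    cohort, _ = simulate_cohort(config)
    cohort = prepare_cohort(cohort)
    result = inference.fit(cohort, covariates, compute_cov=False)
    return result, config

def recovery_experiment(
    base_seed: int = 1,
    n_cohorts: int = 10,
    n_patients: int = 500,
    follow_up_years: float = 6.0,
    covariates: Sequence[str] = RECOVERY_COVARIATES,
) -> dict:
    """Simulate ``n_cohorts`` cohorts, refit each, and average the estimates.

    Returns the generating truth, per-replicate hazard ratios and
    baseline intensities (evaluated at the generating reference
    covariate values for a non-Hispanic patient, so the result is
    invariant to the centering convention used in the fit), and their
    across-replicate means.
    """
    hr_rows = []
    rate_rows = []
    seeds = [(base_seed + i) % 2**31 for i in range(n_cohorts)]
    ref_config = recovery_config(seeds[0], n_patients, follow_up_years)
    reference = ref_config.reference_covariates()
    for seed in seeds:
        config = dataclasses.replace(ref_config, seed=seed)
        result, _ = fit_one_replicate(config, covariates)
        hr_rows.append([result.model.hazard_ratios()[c] for c in covariates])
        rate_rows.append(result.model.rates(
            {c: reference.get(c, 0.0) for c in covariates}
        ))
    hr = np.asarray(hr_rows)
    rates = np.asarray(rate_rows)
    return {
        "seeds": seeds,
        "covariates": tuple(covariates),
        "true_hazard_ratios": dict(ref_config.hazard_ratios),
        "true_rates": {ts: ref_config.baseline_rates[ts] for ts in TRANSITIONS},
        "hazard_ratios": hr,
        "mean_hazard_ratios": dict(zip(covariates, hr.mean(axis=0))),
        "rates": rates,
        "mean_rates": dict(zip(TRANSITIONS, rates.mean(axis=0))),
        "n_patients": n_patients,
        "n_cohorts": n_cohorts,
    }


def selection_experiment(
    base_seed: int = 1,
    n_replicates: int = 20,
    n_patients: int = 500,
    follow_up_years: float = 6.0,
    strong_covariate: str = "hispanic",
    strong_hr: float = 1.5,
    null_covariate: str = "female",
) -> dict:
    """Backward-elimination consistency under one strong and one null effect.

    Each replicate simulates a cohort in which ``strong_covariate`` has
    the given true hazard ratio and ``null_covariate`` has none, runs
    AIC backward elimination from the two-covariate model, and records
    whether the strong covariate was retained and the null one dropped.
    """
    kept_strong = 0
    dropped_null = 0
    correct = 0
    for i in range(n_replicates):
        config = dataclasses.replace(
            recovery_config((base_seed + i) % 2**31, n_patients, follow_up_years),
            hazard_ratios={strong_covariate: strong_hr},
        )
        cohort, _ = simulate_cohort(config)
        cohort = prepare_cohort(cohort)
        final, trace = inference.backward_eliminate(
            cohort, [strong_covariate, null_covariate], compute_cov=False
        )
        kept = set(final.model.covariates)
        dropped = {name for name, _ in trace}
        kept_strong += strong_covariate in kept
        dropped_null += null_covariate in dropped
        correct += (strong_covariate in kept) and (null_covariate in dropped)
    return {
        "n_replicates": n_replicates,
        "kept_strong": kept_strong,
        "dropped_null": dropped_null,
        "correct": correct,
        "fraction_correct": correct / n_replicates,
    }
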