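"""Calibrate monthly transition probabilities from printed cohort summaries.

The source cohort is available only as summary statistics (cumulative
recurrence by median follow-up, stratified 5-/10-year overall survival), so
each transition is fitted as a constant hazard: the minimal-assumption model
for a point survival summary.  A surviving fraction S observed after t months
implies a per-month event probability p = 1 - S**(1/t), i.e. the geometric
(discrete exponential) hazard whose t-month survival is exactly S.

Conventions (documented in the methods note):

* Recurrence is anchored at the median follow-up time, treating the printed
  cumulative recurrence as crude cumulative incidence with no competing-risk
  correction (no at-risk table is available).
* Post-recurrence mortality is anchored on the recurred stratum's 5-year
  survival, measured from recurrence.  The 10-year figure (3.1%) is not
  jointly consistent with a single exponential and is not separately
  enforced.
* Background mortality is anchored on the non-recurred stratum's 10-year
  survival.
* The undetected-to-symptomatic transition is geometric on {1, 2, ...}
  cycles with the stated mean, so p = 1/mean per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .parameters import ClinicalInputs, CohortSummary, ModelConfig, ValidationError


@dataclass(frozen=True)
class TransitionParameters:
    """Monthly transition probabilities consumed by the simulation engine."""

    p_recur_month: float
    p_symptomatic_month: float
    p_die_background_month: float
    p_die_postrecurrence_month: float
    p_operative_death: float
    p_resect_asymptomatic: float
    p_resect_symptomatic: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{f.name} must lie in [0, 1], got {v}")


def monthly_prob_from_survival(surviving_fraction: float, elapsed_months: float) -> float:
    """Constant-hazard monthly event probability implied by a survival summary.

    Parameters
    ----------
    surviving_fraction
        Fraction event-free after `elapsed_months`; must be in (0, 1].
    elapsed_months
        Elapsed time in months; must be > 0.

    Returns
    -------
    float
        ``1 - surviving_fraction ** (1 / elapsed_months)``.
    """
    if not 0.0 < surviving_fraction <= 1.0:
        raise ValidationError(
            f"surviving_fraction must be in (0, 1], got {surviving_fraction} "
            "(zero survival implies an infinite hazard)")
    if elapsed_months <= 0:
        raise ValidationError(f"elapsed_months must be > 0, got {elapsed_months}")
    return 1.0 - surviving_fraction ** (1.0 / elapsed_months)


def calibrate(cohort: CohortSummary, clinical: ClinicalInputs) -> TransitionParameters:
    """Fit all monthly transition probabilities from the cohort summary."""
    return TransitionParameters(
        p_recur_month=monthly_prob_from_survival(
            1.0 - cohort.recurrence_fraction, cohort.median_followup_months),
        p_symptomatic_month=min(
            1.0, 1.0 / clinical.mean_months_undetected_to_symptomatic.value),
        p_die_background_month=monthly_prob_from_survival(cohort.os10_nonrecurred, 120.0),
        p_die_postrecurrence_month=monthly_prob_from_survival(cohort.os5_recurred, 60.0),
        p_operative_death=clinical.metastasectomy_mortality.value,
        p_resect_asymptomatic=clinical.asymptomatic_metastasectomy_rate,
        p_resect_symptomatic=clinical.symptomatic_metastasectomy_rate,
    )


def calibrate_config(config: ModelConfig) -> TransitionParameters:
    """Convenience wrapper: calibrate from a full model configuration."""
    return calibrate(config.cohort, config.clinical)
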