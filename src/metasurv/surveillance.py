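"""Surveillance schedules and per-visit test-panel arithmetic.

Four active follow-up intensities are compared, all combining a clinic
visit, carcinoembryonic-antigen (CEA) test and CT at every scheduled visit,
plus colonoscopy at 1 and 4 years:

========  =====================================================  ======
code      clinic + CEA + CT visits                               visits
========  =====================================================  ======
q3/q12    every 3 months for 2 y, then every 12 months to 5 y      11
q6        every 6 months for 5 y                                   10
q6/q12    every 6 months for 2 y, then every 12 months to 5 y       7
q12       every 12 months for 5 y                                   5
none      no scheduled surveillance (comparator)                    0
========  =====================================================  ======

Visits are anchored at interval ends (month 3, 6, ...), surveillance stops
at month 60, and at most two colonoscopies (months 12 and 48) are performed
over the 10-year horizon.  Tests at one visit are treated as conditionally
independent given disease status, so the panel detects recurrence with
probability 1 - prod(1 - sens_i) and false-alarms (disease absent) with
probability 1 - prod(spec_i).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import CostInputs, TestPerformance

#: Canonical strategy codes, in increasing order of surveillance intensity.
STRATEGY_CODES = ("none", "q12", "q6_q12", "q6", "q3_q12")
#: The four strategies with scheduled surveillance.
ACTIVE_STRATEGIES = ("q12", "q6_q12", "q6", "q3_q12")

_ALIASES = {
    "q6/q12": "q6_q12",
    "q3/q12": "q3_q12",
}

_COLONOSCOPY_MONTHS = (12, 48)


class UnknownStrategyError(ValueError):
    pass


def canonical_code(code: str) -> str:
    """Normalize a strategy code ('q3/q12' and 'q3_q12' are equivalent)."""
    c = _ALIASES.get(code.strip().lower(), code.strip().lower())
    if c not in STRATEGY_CODES:
        raise UnknownStrategyError(
            f"unknown strategy {code!r}; valid codes: {', '.join(STRATEGY_CODES)}")
    return c


@dataclass(frozen=True)
class Schedule:
    """A follow-up calendar: months with a full visit, months with colonoscopy."""

    strategy_code: str
    visit_cycles: frozenset[int]
    colonoscopy_cycles: frozenset[int]

    def __post_init__(self) -> None:
        assert self.colonoscopy_cycles <= self.visit_cycles or not self.colonoscopy_cycles
        assert len(self.colonoscopy_cycles) <= 2


def _visit_months(code: str) -> tuple[int, ...]:
    if code == "none":
        return ()
    if code == "q12":
        return tuple(range(12, 61, 12))
    if code == "q6":
        return tuple(range(6, 61, 6))
    if code == "q6_q12":
        return tuple(range(6, 25, 6)) + (36, 48, 60)
    if code == "q3_q12":
        return tuple(range(3, 25, 3)) + (36, 48, 60)
    raise UnknownStrategyError(code)


def build_schedule(strategy_code: str, horizon_cycles: int = 120) -> Schedule:
    """Build the visit/colonoscopy calendar for a strategy, clipped to the horizon."""
    code = canonical_code(strategy_code)
    visits = frozenset(m for m in _visit_months(code) if 0 < m <= horizon_cycles)
    colos = (frozenset(m for m in _COLONOSCOPY_MONTHS if m in visits)
             if code != "none" else frozenset())
    return Schedule(code, visits, colos)


def panel_sensitivity(tests: TestPerformance, with_colonoscopy: bool = False) -> float:
    """Probability that at least one test at a visit detects existing disease."""
    miss = 1.0
    for t in tests.panel:
        miss *= 1.0 - t.sensitivity.value
    if with_colonoscopy:
        miss *= 1.0 - tests.colonoscopy.sensitivity.value
    return 1.0 - miss


def panel_false_positive(tests: TestPerformance, with_colonoscopy: bool = False) -> float:
    """Probability of at least one positive test at a visit with no disease."""
    clean = 1.0
    for t in tests.panel:
        clean *= t.specificity.value
    if with_colonoscopy:
        clean *= tests.colonoscopy.specificity.value
    return 1.0 - clean


def visit_cost(costs: CostInputs, with_colonoscopy: bool = False,
               confirmatory_workup: bool = False) -> float:
    """Cost of one scheduled visit.

    A confirmatory workup (one extra CT after a false-positive panel) adds
    imaging cost only; it carries no utility decrement and no state change.
    """
    c = costs.clinic_visit + costs.cea_test + costs.ct_scan
    if with_colonoscopy:
        c += costs.colonoscopy
    if confirmatory_workup:
        c += costs.ct_scan
    return c


def schedule_cost(schedule: Schedule, costs: CostInputs) -> float:
    """Undiscounted cost of completing every visit of a schedule (no workups)."""
    total = 0.0
    for m in schedule.visit_cycles:
        total += visit_cost(costs, with_colonoscopy=m in schedule.colonoscopy_cycles)
    return total
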