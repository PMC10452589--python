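"""Monthly-cycle Markov micro-simulation of one post-metastasectomy cohort.

Six health states: no evidence of disease (NED), undetected recurrence,
curative-intent treatment, palliative care for symptomatic or asymptomatic
disease, and dead (absorbing).  Each patient starts in NED and is stepped
through monthly cycles up to the horizon (120 cycles in the base case).

Within a cycle, events resolve in a fixed order:

1. a death draw for the current state — background mortality in NED and
   curative treatment, post-recurrence mortality in the undetected and
   palliative states (mortality follows disease status, not awareness);
2. NED: scheduled visit (cost; possible false-positive confirmatory CT),
   then a recurrence draw;
3. undetected recurrence: symptomatic-conversion draw; symptoms prompt
   presentation the same cycle regardless of schedule.  Otherwise the
   scheduled visit may detect the recurrence with the panel sensitivity;
4. on detection/presentation: a repeat-resection draw (asymptomatic and
   symptomatic patients have different resection rates), an operative-death
   draw if resected, otherwise entry into the matching palliative state;
5. curative treatment lasts a fixed number of cycles (surgery + recovery
   cost on entry, chemotherapy during), then returns to NED with renewed
   recurrence risk;
6. after curative treatment the patient resumes the original calendar
   schedule.

Economic accrual uses mid-cycle discounting, ``(1+r)**(-(c-0.5)/12)``, and a
half-cycle credit in the cycle of death: state-membership utility,
life-years and continuous state costs count half in the cycle a patient
enters the dead state; one-off event costs count in full at the event cycle.

Randomness is organized as a (n_patients, horizon, 7) array of uniforms —
one column per draw type — generated from a single seeded stream.  Patient
``i`` always consumes row ``i`` regardless of cohort size or strategy, which
gives per-patient substreams and common random numbers across strategies.
Two equivalent engines consume the same array: a per-patient reference
implementation that records full trajectories (:func:`simulate_patient`) and
a vectorized cohort engine (:func:`run_cohort`); they agree draw for draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .calibration import TransitionParameters, calibrate_config
from .parameters import ModelConfig
from .surveillance import (Schedule, build_schedule, canonical_code,
                           panel_false_positive, panel_sensitivity, visit_cost)


class HealthState(IntEnum):
    NED = 0
    UNDETECTED_RECURRENCE = 1
    CURATIVE_TREATMENT = 2
    PALLIATIVE_ASYMPTOMATIC = 3
    PALLIATIVE_SYMPTOMATIC = 4
    DEAD = 5


# Draw-type columns of the uniform array.
DRAW_DEATH, DRAW_RECURRENCE, DRAW_SYMPTOMATIC, DRAW_DETECTION, \
    DRAW_RESECTION, DRAW_OPERATIVE, DRAW_FALSE_POSITIVE = range(7)
N_DRAW_TYPES = 7


def monthly_discount_factor(annual_rate: float, cycle: int) -> float:
    """Mid-cycle discount factor for cycle c (1-based): (1+r)^(-(c-0.5)/12)."""
    return (1.0 + annual_rate) ** (-(cycle - 0.5) / 12.0)


def patient_draws(entropy, n_patients: int, n_cycles: int) -> np.ndarray:
    """Uniform draws, shape (n_patients, n_cycles, 7).

    `entropy` seeds a ``numpy.random.SeedSequence`` (an int, or a tuple such
    as ``(seed, psa_draw_index)``).  Row i is a fixed function of (entropy, i):
    the same patient substream is obtained for any cohort size >= i+1, so
    strategies simulated from the same entropy share random numbers.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    return rng.random((n_patients, n_cycles, N_DRAW_TYPES))


# ---------------------------------------------------------------------------
# per-cycle constants derived from a config

@dataclass(frozen=True)
class _EngineInputs:
    """Precomputed per-state costs/utilities and panel probabilities."""

    state_utility: np.ndarray          # utility while occupying each state
    state_cost_month: np.ndarray       # continuous monthly cost of each state
    sens_plain: float
    sens_colo: float
    fp_plain: float
    fp_colo: float
    visit_cost_plain: float
    visit_cost_colo: float
    confirmatory_ct: float
    resection_one_off: float           # surgery + recovery (+ chemo course if per-episode)
    palliative_entry_cost: float       # chemo course on palliative entry (per-episode mode)
    fp_workup: bool
    duration_cur: int
    discount_rate: float


def _engine_inputs(config: ModelConfig) -> _EngineInputs:
    u, c, s = config.utilities, config.costs, config.settings
    monthly = s.chemo_charging == "monthly"
    state_utility = np.array([
        u.ned, u.undetected_recurrence, u.curative_treatment,
        u.palliative_asymptomatic, u.palliative_symptomatic, 0.0])
    state_cost = np.array([
        0.0, 0.0,
        c.curative_chemo_month if monthly else 0.0,
        c.palliative_chemo_month if monthly else 0.0,
        c.palliative_chemo_month if monthly else 0.0,
        0.0])
    resection = c.hepatic_metastasectomy + c.post_anesthesia_recovery
    if not monthly:
        resection += c.curative_chemo_month
    return _EngineInputs(
        state_utility=state_utility,
        state_cost_month=state_cost,
        sens_plain=panel_sensitivity(config.tests, False),
        sens_colo=panel_sensitivity(config.tests, True),
        fp_plain=panel_false_positive(config.tests, False),
        fp_colo=panel_false_positive(config.tests, True),
        visit_cost_plain=visit_cost(c, False),
        visit_cost_colo=visit_cost(c, True),
        confirmatory_ct=c.ct_scan,
        resection_one_off=resection,
        palliative_entry_cost=0.0 if monthly else c.palliative_chemo_month,
        fp_workup=s.false_positive_workup,
        duration_cur=config.clinical.curative_treatment_duration,
        discount_rate=s.annual_discount_rate,
    )


# ---------------------------------------------------------------------------
# scalar reference engine

@dataclass
class CycleRecord:
    """One cycle of one patient: state occupied, events, accruals."""

    cycle: int
    state: HealthState
    events: frozenset[str]
    one_off_cost: float
    state_cost_month: float
    utility: float
    occupancy: float  # 1.0, or 0.5 in the cycle of entry into DEAD


@dataclass
class PatientTrajectory:
    """Full per-cycle record of one simulated patient."""

    records: list[CycleRecord] = field(default_factory=list)

    @property
    def final_state(self) -> HealthState:
        if self.records and "death" in self.records[-1].events:
            return HealthState.DEAD
        return self.records[-1].state if self.records else HealthState.NED

    def n_events(self, name: str) -> int:
        return sum(name in r.events for r in self.records)


def step_patient(state: HealthState, cycle: int, months_in_treatment: int,
                 tp: TransitionParameters, schedule: Schedule,
                 config: ModelConfig, draws: np.ndarray,
                 ) -> tuple[HealthState, int, frozenset[str], float]:
    """Advance one patient by one cycle.

    `draws` is the 7-vector of uniforms for this (patient, cycle).  Returns
    (next_state, months_in_treatment, events, one_off_cost).  Continuous
    state costs and utilities are functions of the current state and are
    accrued by the caller.
    """
    if state is HealthState.DEAD:
        return HealthState.DEAD, 0, frozenset(), 0.0
    e = _engine_inputs(config)
    events: set[str] = set()
    cost = 0.0
    p_die = (tp.p_die_background_month
             if state in (HealthState.NED, HealthState.CURATIVE_TREATMENT)
             else tp.p_die_postrecurrence_month)
    if draws[DRAW_DEATH] < p_die:
        return HealthState.DEAD, 0, frozenset({"death"}), 0.0

    next_state = state
    on_visit = cycle in schedule.visit_cycles
    colo = cycle in schedule.colonoscopy_cycles

    def attend_visit() -> None:
        nonlocal cost
        events.add("scheduled_visit")
        cost += e.visit_cost_colo if colo else e.visit_cost_plain
        if colo:
            events.add("colonoscopy")

    def detection_outcome(asymptomatic: bool) -> HealthState:
        nonlocal cost
        p_res = tp.p_resect_asymptomatic if asymptomatic else tp.p_resect_symptomatic
        if draws[DRAW_RESECTION] < p_res:
            events.add("metastasectomy")
            cost += e.resection_one_off
            if draws[DRAW_OPERATIVE] < tp.p_operative_death:
                events.update(("operative_death", "death"))
                return HealthState.DEAD
            return HealthState.CURATIVE_TREATMENT
        cost += e.palliative_entry_cost
        return (HealthState.PALLIATIVE_ASYMPTOMATIC if asymptomatic
                else HealthState.PALLIATIVE_SYMPTOMATIC)

    if state is HealthState.NED:
        if on_visit:
            attend_visit()
            if e.fp_workup and draws[DRAW_FALSE_POSITIVE] < (e.fp_colo if colo else e.fp_plain):
                events.add("false_positive")
                cost += e.confirmatory_ct
        if draws[DRAW_RECURRENCE] < tp.p_recur_month:
            events.add("recurrence")
            next_state = HealthState.UNDETECTED_RECURRENCE
    elif state is HealthState.UNDETECTED_RECURRENCE:
        if draws[DRAW_SYMPTOMATIC] < tp.p_symptomatic_month:
            events.add("symptomatic_presentation")
            next_state = detection_outcome(asymptomatic=False)
        elif on_visit:
            attend_visit()
            if draws[DRAW_DETECTION] < (e.sens_colo if colo else e.sens_plain):
                events.add("detection_asymptomatic")
                next_state = detection_outcome(asymptomatic=True)
    elif state is HealthState.CURATIVE_TREATMENT:
        months_in_treatment += 1
        if months_in_treatment >= e.duration_cur:
            next_state = HealthState.NED
            months_in_treatment = 0
    # palliative states: only the death draw above can move the patient

    if next_state is HealthState.CURATIVE_TREATMENT and state is not HealthState.CURATIVE_TREATMENT:
        months_in_treatment = 0
    if next_state is HealthState.DEAD:
        events.add("death")
    return next_state, months_in_treatment, frozenset(events), cost


def simulate_patient(config: ModelConfig, schedule: Schedule,
                     tp: TransitionParameters, draws: np.ndarray) -> PatientTrajectory:
    """Simulate one patient over the horizon; `draws` has shape (horizon, 7)."""
    e = _engine_inputs(config)
    horizon = config.settings.horizon_cycles
    traj = PatientTrajectory()
    state = HealthState.NED
    months = 0
    for cycle in range(1, horizon + 1):
        nxt, months, events, one_off = step_patient(
            state, cycle, months, tp, schedule, config, draws[cycle - 1])
        occupancy = 0.5 if nxt is HealthState.DEAD else 1.0
        traj.records.append(CycleRecord(
            cycle=cycle, state=state, events=events, one_off_cost=one_off,
            state_cost_month=float(e.state_cost_month[state]),
            utility=float(e.state_utility[state]), occupancy=occupancy))
        if nxt is HealthState.DEAD:
            break
        state = nxt
    return traj


def accrue(trajectory: PatientTrajectory, config: ModelConfig,
           ) -> tuple[float, float, float]:
    """Discounted (cost, QALY, LY) of one trajectory (half-cycle corrected)."""
    r = config.settings.annual_discount_rate
    cost = qaly = ly = 0.0
    for rec in trajectory.records:
        df = monthly_discount_factor(r, rec.cycle)
        cost += (rec.one_off_cost + rec.state_cost_month * rec.occupancy) * df
        qaly += rec.utility * rec.occupancy / 12.0 * df
        ly += rec.occupancy / 12.0 * df
    return cost, qaly, ly


# ---------------------------------------------------------------------------
# vectorized cohort engine

@dataclass
class CohortArrays:
    """Per-patient outcomes of one simulated cohort."""

    cost: np.ndarray
    qaly: np.ndarray
    ly: np.ndarray
    colonoscopies: np.ndarray
    detected_asymptomatic: np.ndarray
    symptomatic_presentation: np.ndarray
    resections: np.ndarray
    alive_at_horizon: np.ndarray
    occupancy_by_cycle: np.ndarray  # (horizon, 6) mean state occupancy


@dataclass(frozen=True)
class StrategyResult:
    """Mean discounted outcomes of one strategy (with Monte Carlo error)."""

    strategy_code: str
    mean_cost: float
    mean_qaly: float
    mean_ly: float
    se_cost: float
    se_qaly: float
    se_ly: float
    n_patients: int
    seed: int | tuple
    cohort: CohortArrays = field(repr=False, compare=False, default=None)


def run_cohort(config: ModelConfig, schedule: Schedule, tp: TransitionParameters,
               n_patients: int, entropy, draws: np.ndarray | None = None,
               ) -> CohortArrays:
    """Simulate `n_patients` trajectories at once (same model as the scalar path)."""
    e = _engine_inputs(config)
    H = config.settings.horizon_cycles
    if draws is None:
        draws = patient_draws(entropy, n_patients, H)
    n = n_patients
    state = np.full(n, int(HealthState.NED), dtype=np.int8)
    months_tx = np.zeros(n, dtype=np.int16)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    ly = np.zeros(n)
    colono = np.zeros(n, dtype=np.int16)
    detected = np.zeros(n, dtype=bool)
    sympt_ever = np.zeros(n, dtype=bool)
    resections = np.zeros(n, dtype=np.int16)
    occ_by_cycle = np.zeros((H, len(HealthState)))

    NED = int(HealthState.NED)
    UND = int(HealthState.UNDETECTED_RECURRENCE)
    CUR = int(HealthState.CURATIVE_TREATMENT)
    PA = int(HealthState.PALLIATIVE_ASYMPTOMATIC)
    PS = int(HealthState.PALLIATIVE_SYMPTOMATIC)
    DEAD = int(HealthState.DEAD)

    for c in range(1, H + 1):
        for s in range(len(HealthState)):
            occ_by_cycle[c - 1, s] = np.mean(state == s)
        uc = draws[:, c - 1, :]
        df = monthly_discount_factor(e.discount_rate, c)
        alive = state != DEAD
        if not alive.any():
            occ_by_cycle[c - 1:, DEAD] = 1.0
            break
        background = (state == NED) | (state == CUR)
        p_die = np.where(background, tp.p_die_background_month,
                         tp.p_die_postrecurrence_month)
        draw_death = alive & (uc[:, DRAW_DEATH] < p_die)
        survivors = alive & ~draw_death
        one_off = np.zeros(n)
        new_state = state.copy()
        new_state[draw_death] = DEAD

        on_visit = c in schedule.visit_cycles
        is_colo = c in schedule.colonoscopy_cycles
        vc = e.visit_cost_colo if is_colo else e.visit_cost_plain
        sens = e.sens_colo if is_colo else e.sens_plain
        fp_p = e.fp_colo if is_colo else e.fp_plain

        ned = survivors & (state == NED)
        if on_visit:
            one_off[ned] += vc
            if is_colo:
                colono[ned] += 1
            if e.fp_workup:
                fp = ned & (uc[:, DRAW_FALSE_POSITIVE] < fp_p)
                one_off[fp] += e.confirmatory_ct
        recur = ned & (uc[:, DRAW_RECURRENCE] < tp.p_recur_month)
        new_state[recur] = UND

        und = survivors & (state == UND)
        sympt = und & (uc[:, DRAW_SYMPTOMATIC] < tp.p_symptomatic_month)
        sympt_ever |= sympt
        det = np.zeros(n, dtype=bool)
        if on_visit:
            att = und & ~sympt
            one_off[att] += vc
            if is_colo:
                colono[att] += 1
            det = att & (uc[:, DRAW_DETECTION] < sens)
            detected |= det
        for group, p_res, pall in ((sympt, tp.p_resect_symptomatic, PS),
                                   (det, tp.p_resect_asymptomatic, PA)):
            res = group & (uc[:, DRAW_RESECTION] < p_res)
            one_off[res] += e.resection_one_off
            resections[res] += 1
            op_death = res & (uc[:, DRAW_OPERATIVE] < tp.p_operative_death)
            new_state[op_death] = DEAD
            new_state[res & ~op_death] = CUR
            months_tx[res & ~op_death] = 0
            no_res = group & ~res
            new_state[no_res] = pall
            one_off[no_res] += e.palliative_entry_cost

        cur = survivors & (state == CUR)
        months_tx[cur] += 1
        done = cur & (months_tx >= e.duration_cur)
        new_state[done] = NED
        months_tx[done] = 0

        died_now = alive & (new_state == DEAD)
        occupancy = alive.astype(float)
        occupancy[died_now] = 0.5
        cost += (one_off + e.state_cost_month[state] * occupancy) * df
        qaly += e.state_utility[state] * occupancy / 12.0 * df
        ly += occupancy / 12.0 * df
        state = new_state

    return CohortArrays(cost=cost, qaly=qaly, ly=ly, colonoscopies=colono,
                        detected_asymptomatic=detected,
                        symptomatic_presentation=sympt_ever,
                        resections=resections,
                        alive_at_horizon=state != DEAD,
                        occupancy_by_cycle=occ_by_cycle)


def run_strategy(config: ModelConfig, strategy_code: str,
                 n_patients: int | None = None, seed: int | None = None,
                 tp: TransitionParameters | None = None, draw_index: int = 0,
                 draws: np.ndarray | None = None) -> StrategyResult:
    """Calibrate, build the schedule and simulate one strategy.

    The random stream is keyed by ``(seed, draw_index)``; the base case uses
    draw_index 0 and the probabilistic sensitivity analysis uses one index
    per draw.  Identical (config, seed, n_patients) give bit-identical
    results, and different strategies at the same key share random numbers.
    """
    code = canonical_code(strategy_code)
    n = n_patients if n_patients is not None else config.settings.n_patients
    sd = seed if seed is not None else config.settings.rng_seed
    tp = tp if tp is not None else calibrate_config(config)
    schedule = build_schedule(code, config.settings.horizon_cycles)
    arrays = run_cohort(config, schedule, tp, n, (sd, draw_index), draws=draws)
    sqn = max(n, 2)

    def mse(x: np.ndarray) -> tuple[float, float]:
        return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(sqn))

    mc, sc = mse(arrays.cost)
    mq, sq = mse(arrays.qaly)
    ml, sl = mse(arrays.ly)
    return StrategyResult(strategy_code=code, mean_cost=mc, mean_qaly=mq,
                          mean_ly=ml, se_cost=sc, se_qaly=sq, se_ly=sl,
                          n_patients=n, seed=sd, cohort=arrays)


def trajectory_frame(trajectory: PatientTrajectory):
    """Per-cycle event log of one trajectory as a DataFrame (audit export)."""
    import pandas as pd

    return pd.DataFrame({
        "cycle": [r.cycle for r in trajectory.records],
        "state": [HealthState(r.state).name for r in trajectory.records],
        "events": ["|".join(sorted(r.events)) for r in trajectory.records],
        "one_off_cost": [r.one_off_cost for r in trajectory.records],
        "state_cost_month": [r.state_cost_month for r in trajectory.records],
        "utility": [r.utility for r in trajectory.records],
        "occupancy": [r.occupancy for r in trajectory.records],
    })
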