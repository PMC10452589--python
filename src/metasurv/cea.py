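"""Incremental cost-effectiveness analysis, PSA, CEAC, and deterministic SA.

The incremental table ranks strategies by ascending cost, removes
absolutely dominated strategies (at least as costly and at most as
effective as some alternative, with one strict inequality), then computes
ICERs against the previous surviving row and iteratively removes
extended-dominated strategies (ICER exceeding that of the next surviving
row) until ICERs are non-decreasing along the frontier.  Collinear
strategies (equal consecutive ICERs) are retained.

Published incremental tables are conventionally printed row against
previous row even when the previous row is dominated, so each row also
carries the adjacent-row deltas and ICER alongside the frontier ones.

The probabilistic sensitivity analysis redraws every parameter with an
assigned gamma/beta distribution (moment-matched to the printed mean and
spread, ranges read as 95% intervals) and re-runs the micro-simulation per
draw with common random numbers across strategies.  Cost-effectiveness
acceptability curves report, per willingness-to-pay value, the fraction of
draws in which each strategy maximizes net monetary benefit
(lambda * QALY - cost); ties are split equally so curves sum to one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import calibrate_config
from .microsim import StrategyResult, patient_draws, run_strategy
from .parameters import ModelConfig, get_param, set_param
from .surveillance import ACTIVE_STRATEGIES, canonical_code

logger = logging.getLogger(__name__)

REFERENCE, FRONTIER = "reference", "frontier"
ABS_DOMINATED, EXT_DOMINATED = "absolutely_dominated", "extended_dominated"


@dataclass(frozen=True)
class IncrementalRow:
    """One line of the dominance-annotated incremental table."""

    strategy_code: str
    cost: float
    effect: float
    status: str                       # reference | frontier | *_dominated
    delta_cost: float | None          # vs previous surviving (frontier) row
    delta_effect: float | None
    icer: float | None
    delta_cost_adjacent: float | None  # vs previous row in cost order, as printed
    delta_effect_adjacent: float | None
    icer_adjacent: float | None


def _as_points(results) -> list[tuple[str, float, float]]:
    pts = []
    for r in results:
        if isinstance(r, StrategyResult):
            pts.append((r.strategy_code, r.mean_cost, r.mean_qaly))
        else:
            code, cost, eff = r
            pts.append((code, float(cost), float(eff)))
    codes = [p[0] for p in pts]
    if len(set(codes)) != len(codes):
        raise ValueError(f"duplicate strategy codes in {codes}")
    return pts


def incremental_table(results, effect: str = "qaly") -> list[IncrementalRow]:
    """Dominance-annotated ICER table from (strategy, cost, effect) results.

    `results` is a list of (code, cost, effect) triples or
    :class:`StrategyResult` objects (`effect` then selects 'qaly' or 'ly').
    Rows are returned in ascending cost order.
    """
    if isinstance(results[0] if results else None, StrategyResult) and effect == "ly":
        pts = [(r.strategy_code, r.mean_cost, r.mean_ly) for r in results]
    else:
        pts = _as_points(results)
    if len(pts) < 1:
        raise ValueError("need at least one strategy")
    order = sorted(range(len(pts)), key=lambda i: (pts[i][1], pts[i][2]))
    codes = [pts[i][0] for i in order]
    costs = [pts[i][1] for i in order]
    effs = [pts[i][2] for i in order]
    n = len(codes)

    status = [FRONTIER] * n
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if (costs[j] <= costs[i] and effs[j] >= effs[i]
                    and (costs[j] < costs[i] or effs[j] > effs[i])):
                status[i] = ABS_DOMINATED
                break

    def surviving() -> list[int]:
        return [i for i in range(n) if status[i] in (FRONTIER, REFERENCE)]

    # iterative extended dominance (strict: equal ICERs are retained)
    while True:
        surv = surviving()
        icers = []
        for k in range(1, len(surv)):
            a, b = surv[k - 1], surv[k]
            de = effs[b] - effs[a]
            icers.append((costs[b] - costs[a]) / de if de != 0 else math.inf)
        eliminated = False
        for k in range(len(icers) - 1):
            if icers[k] > icers[k + 1]:
                status[surv[k + 1]] = EXT_DOMINATED
                eliminated = True
                break
        if icers and icers[-1] == math.inf:
            status[surv[-1]] = EXT_DOMINATED
            eliminated = True
        if not eliminated:
            break

    surv = surviving()
    if surv:
        status[surv[0]] = REFERENCE

    rows = []
    prev_surv: int | None = None
    for idx, i in enumerate(range(n)):
        dc = de = icer = None
        if status[i] in (FRONTIER,) and prev_surv is not None:
            dc = costs[i] - costs[prev_surv]
            de = effs[i] - effs[prev_surv]
            icer = dc / de if de != 0 else math.inf
        dca = deca = icera = None
        if idx > 0:
            dca = costs[i] - costs[i - 1]
            deca = effs[i] - effs[i - 1]
            icera = dca / deca if deca != 0 else math.inf
        rows.append(IncrementalRow(
            strategy_code=codes[i], cost=costs[i], effect=effs[i],
            status=status[i], delta_cost=dc, delta_effect=de, icer=icer,
            delta_cost_adjacent=dca, delta_effect_adjacent=deca,
            icer_adjacent=icera))
        if status[i] in (REFERENCE, FRONTIER):
            prev_surv = i
    return rows


def incremental_frame(rows: list[IncrementalRow], effect_label: str = "qaly",
                      ) -> pd.DataFrame:
    """Incremental table as a DataFrame (CSV-ready, published-table shape)."""
    return pd.DataFrame([{
        "strategy": r.strategy_code,
        "cost": r.cost,
        effect_label: r.effect,
        "status": r.status,
        "delta_cost": r.delta_cost,
        f"delta_{effect_label}": r.delta_effect,
        "icer": r.icer,
        "delta_cost_vs_previous_row": r.delta_cost_adjacent,
        f"delta_{effect_label}_vs_previous_row": r.delta_effect_adjacent,
        "icer_vs_previous_row": r.icer_adjacent,
    } for r in rows])


def frontier(rows: list[IncrementalRow]) -> list[str]:
    """Codes of the surviving (non-dominated) strategies, cheapest first."""
    return [r.strategy_code for r in rows if r.status in (REFERENCE, FRONTIER)]


def frontier_oracle(results) -> set[str]:
    """Brute-force frontier via net-monetary-benefit scans (test oracle).

    A strategy is on the frontier iff it maximizes lambda*effect - cost for
    some willingness-to-pay lambda >= 0.  Candidate lambdas are every
    pairwise positive slope plus midpoints and extremes, which is exhaustive
    for finitely many points.  Independent of :func:`incremental_table`.
    """
    pts = _as_points(results)
    codes = [p[0] for p in pts]
    costs = np.array([p[1] for p in pts])
    effs = np.array([p[2] for p in pts])
    slopes = sorted({(costs[j] - costs[i]) / (effs[j] - effs[i])
                     for i in range(len(pts)) for j in range(len(pts))
                     if effs[j] != effs[i]
                     and (costs[j] - costs[i]) / (effs[j] - effs[i]) > 0})
    cands = [1e-12]
    for k, s in enumerate(slopes):
        cands.append(s)
        if k + 1 < len(slopes):
            cands.append(0.5 * (s + slopes[k + 1]))
    cands.append((slopes[-1] * 2 + 1) if slopes else 1.0)
    surv: set[str] = set()
    for lam in cands:
        nmb = lam * effs - costs
        m = nmb.max()
        tol = 1e-9 * max(1.0, abs(m))
        surv.update(codes[i] for i in np.flatnonzero(nmb >= m - tol))
    return surv


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

def sample_psa_config(config: ModelConfig, rng: np.random.Generator) -> ModelConfig:
    """One PSA parameter draw: resample every non-fixed parameter.

    Gamma parameters are moment-matched (shape = (m/sd)^2, scale = sd^2/m);
    beta parameters match mean and sd with infeasible sds clamped (logged).
    Degenerate entries (sd = 0, or a beta mean on the boundary such as a
    perfect specificity) pass through unchanged.
    """
    cfg = config
    for path, dist in config.psa_distributions.items():
        if dist.family == "fixed" or not dist.sd:
            continue
        m, sd = dist.mean, dist.sd
        if dist.family == "gamma":
            shape = (m / sd) ** 2
            x = float(rng.gamma(shape, sd * sd / m))
        else:  # beta
            if m <= 0.0 or m >= 1.0:
                logger.warning("PSA: beta mean on boundary for %s; left fixed", path)
                continue
            v, vmax = sd * sd, m * (1.0 - m)
            if v >= vmax:
                logger.warning("PSA: sd %.4g infeasible for beta mean %.4g at %s; clamped",
                               sd, m, path)
                v = 0.98 * vmax
            k = vmax / v - 1.0
            x = float(rng.beta(m * k, (1.0 - m) * k))
        if path == "clinical.mean_months_undetected_to_symptomatic":
            x = max(x, 1.0)
        cfg = set_param(cfg, path, x)
    return cfg


@dataclass
class PsaResult:
    """Draw-level PSA outcomes: cost/QALY per (draw, strategy)."""

    strategies: tuple[str, ...]
    cost: np.ndarray   # (n_draws, n_strategies)
    qaly: np.ndarray
    n_draws: int
    n_patients_per_draw: int
    seed: int

    def plane_frame(self) -> pd.DataFrame:
        recs = []
        for d in range(self.n_draws):
            for s, code in enumerate(self.strategies):
                recs.append({"draw": d, "strategy": code,
                             "cost": self.cost[d, s], "qaly": self.qaly[d, s]})
        return pd.DataFrame(recs)


def run_psa(config: ModelConfig, n_draws: int | None = None,
            n_patients_per_draw: int | None = None, seed: int | None = None,
            strategies=ACTIVE_STRATEGIES) -> PsaResult:
    """Joint resampling of all uncertain inputs, one micro-simulation per draw.

    Draw d samples parameters from a stream keyed (seed, d, 1) and simulates
    every strategy with patient draws keyed (seed, d) — common random numbers
    across strategies within a draw.  Draw 0 of an all-fixed config is
    bit-identical to the base-case run at the same seed.
    """
    s = config.settings
    n_draws = n_draws if n_draws is not None else s.n_psa_draws
    n_pat = (n_patients_per_draw if n_patients_per_draw is not None
             else s.n_patients_per_psa_draw)
    seed = seed if seed is not None else s.rng_seed
    strategies = tuple(canonical_code(c) for c in strategies)
    cost = np.empty((n_draws, len(strategies)))
    qaly = np.empty((n_draws, len(strategies)))
    H = s.horizon_cycles
    for d in range(n_draws):
        prm_rng = np.random.default_rng(np.random.SeedSequence((seed, d, 1)))
        cfg = sample_psa_config(config, prm_rng)
        tp = calibrate_config(cfg)
        draws = patient_draws((seed, d), n_pat, H)
        for si, code in enumerate(strategies):
            res = run_strategy(cfg, code, n_patients=n_pat, seed=seed,
                               tp=tp, draw_index=d, draws=draws)
            cost[d, si] = res.mean_cost
            qaly[d, si] = res.mean_qaly
    return PsaResult(strategies=strategies, cost=cost, qaly=qaly,
                     n_draws=n_draws, n_patients_per_draw=n_pat, seed=seed)


def ceac(psa: PsaResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves (long format).

    For each willingness-to-pay value, the probability that each strategy
    maximizes net monetary benefit across PSA draws; NMB ties within a draw
    are split equally, so probabilities sum to one at every threshold.
    """
    recs = []
    for lam in wtp_grid:
        nmb = lam * psa.qaly - psa.cost
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-9 * np.maximum(1.0, np.abs(best))
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        for code, p in zip(psa.strategies, probs):
            recs.append({"strategy": code, "wtp": float(lam),
                         "probability_cost_effective": float(p)})
    return pd.DataFrame(recs)


def ceac_maximizer(ceac_frame: pd.DataFrame, wtp: float) -> str:
    """Strategy with the highest acceptability at one threshold."""
    sub = ceac_frame[ceac_frame["wtp"] == wtp]
    return sub.loc[sub["probability_cost_effective"].idxmax(), "strategy"]


# ---------------------------------------------------------------------------
# deterministic sensitivity analyses

def run_scenario(config: ModelConfig, overrides: dict[str, float],
                 strategies=ACTIVE_STRATEGIES, n_patients: int | None = None,
                 seed: int | None = None) -> list[StrategyResult]:
    """Apply parameter overrides, re-calibrate, and simulate each strategy."""
    cfg = config
    for path, value in overrides.items():
        get_param(config, path)  # raise early, naming known paths
        cfg = set_param(cfg, path, value)
    tp = calibrate_config(cfg)
    return [run_strategy(cfg, code, n_patients=n_patients, seed=seed, tp=tp)
            for code in strategies]


def one_way_dsa(config: ModelConfig, param_path: str, values,
                strategies=ACTIVE_STRATEGIES, n_patients: int | None = None,
                seed: int | None = None, reference: str = "q12") -> pd.DataFrame:
    """One-way sensitivity analysis: re-run the base case per parameter value.

    Returns one row per (value, strategy) with the strategy's dominance
    status from the incremental table and its pairwise ICER against the
    reference strategy (the published comparison convention).
    """
    scenarios = [(f"{param_path}={v}", {param_path: v}) for v in values]
    return scenario_table(config, scenarios, strategies, n_patients, seed, reference)


def scenario_table(config: ModelConfig, scenarios, strategies=ACTIVE_STRATEGIES,
                   n_patients: int | None = None, seed: int | None = None,
                   reference: str = "q12") -> pd.DataFrame:
    """Run labelled override scenarios and tabulate dominance/ICER vs reference."""
    reference = canonical_code(reference)
    recs = []
    for label, overrides in scenarios:
        results = run_scenario(config, overrides, strategies, n_patients, seed)
        rows = {r.strategy_code: r for r in
                incremental_table(results, effect="qaly")}
        ref = next(r for r in results if r.strategy_code == reference)
        for res in results:
            row = rows[res.strategy_code]
            if res.strategy_code == reference:
                icer_vs_ref = None
            else:
                dq = res.mean_qaly - ref.mean_qaly
                icer_vs_ref = ((res.mean_cost - ref.mean_cost) / dq
                               if dq != 0 else math.inf)
            recs.append({
                "scenario": label, "strategy": res.strategy_code,
                "cost": res.mean_cost, "qaly": res.mean_qaly,
                "status": row.status, "icer_vs_" + reference: icer_vs_ref,
            })
    return pd.DataFrame(recs)


def resection_rate_scenarios(config: ModelConfig) -> list[tuple[str, dict[str, float]]]:
    """The +/-25% opposite-direction repeat-resection scenarios.

    The asymptomatic/symptomatic rate gap is widened (asymptomatic up 25%,
    symptomatic down 25%) and narrowed (the reverse), bracketing the
    plausible difference between the observed rates.
    """
    a = config.clinical.asymptomatic_metastasectomy_rate
    s = config.clinical.symptomatic_metastasectomy_rate
    return [
        ("resection_gap_decreased_25pct",
         {"clinical.asymptomatic_metastasectomy_rate": a * 0.75,
          "clinical.symptomatic_metastasectomy_rate": s * 1.25}),
        ("resection_gap_increased_25pct",
         {"clinical.asymptomatic_metastasectomy_rate": a * 1.25,
          "clinical.symptomatic_metastasectomy_rate": s * 0.75}),
    ]


def dsa_presets(config: ModelConfig) -> dict[str, list[tuple[str, dict[str, float]]]]:
    """Named deterministic-SA scenario sets."""
    path = "clinical.mean_months_undetected_to_symptomatic"
    return {
        "time_to_symptomatic": [(f"{path}={v}", {path: float(v)})
                                for v in (1, 4, 28)],
        "resection_rates": resection_rate_scenarios(config),
    }


def two_way_dsa(config: ModelConfig, param_a: str, values_a, param_b: str,
                values_b, wtp: float = 50_000.0, strategies=ACTIVE_STRATEGIES,
                n_patients: int | None = None, seed: int | None = None,
                ) -> pd.DataFrame:
    """Grid of the NMB-maximizing strategy at one threshold over two parameters."""
    recs = []
    for va in values_a:
        for vb in values_b:
            results = run_scenario(config, {param_a: va, param_b: vb},
                                   strategies, n_patients, seed)
            nmb = [(wtp * r.mean_qaly - r.mean_cost, r.strategy_code)
                   for r in results]
            recs.append({param_a: va, param_b: vb,
                         "preferred_strategy": max(nmb)[1]})
    return pd.DataFrame(recs)
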