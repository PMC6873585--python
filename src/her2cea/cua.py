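"""Cost-utility accounting: discounted costs, LYs, QALYs, ICERs, NMB,
and the threshold (cost-effective) price of the trastuzumab bundle.

Costs and outcomes are discounted at the same annual rate with
first-year flows undiscounted (factor ``(1+r)^-(t-1)``).  The one-off
treatment-course cost is charged at cycle 1; state costs and utilities
accrue per cycle in proportion to state occupancy, with the first-year
tunnel states carrying their own cost rows.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .markov import ALIVE, ARM_CHEMO, ARM_TRASTUZUMAB, CohortTrace, HealthState, N_STATES, run_cohort
from .params import ParameterSet, ParameterTable

__all__ = [
    "ArmOutcome",
    "CEResult",
    "Perspective",
    "accumulate_outcomes",
    "compute_icer",
    "deterministic_results",
    "discount_factor",
    "net_monetary_benefit",
    "run_arm",
    "state_cost_vector",
    "state_utility_vector",
    "threshold_price_search",
]


class Perspective(str, enum.Enum):
    """Costing perspective: the healthcare system pays direct medical costs
    only; the societal perspective adds direct non-medical costs."""

    HEALTHCARE = "healthcare_system"
    SOCIETAL = "societal"


@dataclass(frozen=True)
class ArmOutcome:
    """Total lifetime cost (PHP), life-years and QALYs for one arm."""

    arm: str
    perspective: Perspective
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float


class Dominance(str, enum.Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention_dominant"
    INTERVENTION_DOMINATED = "intervention_dominated"


@dataclass(frozen=True)
class CEResult:
    """Incremental results of intervention vs control (same perspective)."""

    perspective: Perspective
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_ly: float | None
    icer_per_qaly: float | None
    dominance: Dominance


def discount_factor(cycle: int, rate: float, from_first_cycle: bool = True) -> float:
    """Discount factor for a 1-based cycle; first-year flows undiscounted."""
    if cycle < 1:
        raise ValueError(f"cycle must be >= 1 (got {cycle})")
    if rate < 0:
        raise ValueError(f"rate must be >= 0 (got {rate})")
    exponent = cycle - 1 if from_first_cycle else cycle
    return (1.0 + rate) ** -exponent


def state_cost_vector(ps: ParameterSet, perspective: Perspective) -> np.ndarray:
    """Annual cost per state (PHP), in HealthState order; DEATH costs nothing."""
    rec_later, dnmc_rec_later = "dmc_rec_later", "dnmc_rec_later"
    if ps.settings.recurrence_later_costs == "alternate":
        rec_later, dnmc_rec_later = "dmc_rec_later_alt", "dnmc_rec_later_alt"
        if ps.get(rec_later) is None or ps.get(dnmc_rec_later) is None:
            raise KeyError("alternate recurrence cost rows not present in parameter set")
    names = ["dmc_dfs", "dmc_chf", "dmc_rec_y1", rec_later, "dmc_met_y1", "dmc_met_later"]
    costs = np.array([ps[n] for n in names] + [0.0])
    if perspective is Perspective.SOCIETAL:
        dn = ["dnmc_dfs", "dnmc_chf", "dnmc_rec_y1", dnmc_rec_later, "dnmc_met_y1", "dnmc_met_later"]
        costs = costs + np.array([ps[n] for n in dn] + [0.0])
    return costs


def state_utility_vector(ps: ParameterSet) -> np.ndarray:
    """Utility weight per state; tunnel sub-states share their state's utility."""
    return np.array([
        ps["u_dfs"], ps["u_chf"], ps["u_rec"], ps["u_rec"], ps["u_met"], ps["u_met"], 0.0,
    ])


def treatment_course_cost(ps: ParameterSet, arm: str, perspective: Perspective) -> float:
    """One-off per-patient treatment-course cost charged at cycle 1."""
    dmc = ps["dmc_tx_trast"] if arm == ARM_TRASTUZUMAB else ps["dmc_tx_ct"]
    if perspective is Perspective.SOCIETAL:
        dmc += ps["dnmc_tx_trast"] if arm == ARM_TRASTUZUMAB else ps["dnmc_tx_ct"]
    return dmc


def accumulate_outcomes(trace: CohortTrace, ps: ParameterSet,
                        perspective: Perspective = Perspective.HEALTHCARE) -> ArmOutcome:
    """Occupancy-weighted costs, LYs and QALYs, discounted and undiscounted."""
    st = ps.settings
    occ = trace.occupancy
    if st.half_cycle:
        # trapezoid correction: average start- and end-of-cycle occupancy
        entry = np.zeros(N_STATES)
        entry[HealthState.DFS] = 1.0
        occ = 0.5 * (np.vstack([entry, occ[:-1]]) + occ)
    cycles = np.arange(1, trace.horizon + 1)
    disc = (1.0 + st.discount_rate) ** -(cycles - 1 if st.discount_from_first_cycle else cycles)

    cost_flow = occ @ state_cost_vector(ps, perspective)
    cost_flow = cost_flow.copy()
    cost_flow[0] += treatment_course_cost(ps, trace.arm, perspective)
    ly_flow = occ @ ALIVE.astype(float)
    qaly_flow = occ @ state_utility_vector(ps)

    return ArmOutcome(
        arm=trace.arm,
        perspective=perspective,
        cost=float(disc @ cost_flow),
        ly=float(disc @ ly_flow),
        qaly=float(disc @ qaly_flow),
        cost_undiscounted=float(cost_flow.sum()),
        ly_undiscounted=float(ly_flow.sum()),
        qaly_undiscounted=float(qaly_flow.sum()),
    )


def run_arm(ps: ParameterSet, arm: str,
            perspective: Perspective = Perspective.HEALTHCARE) -> ArmOutcome:
    """Cohort simulation plus outcome accumulation for one arm."""
    return accumulate_outcomes(run_cohort(ps, arm), ps, perspective)


def compute_icer(intervention: ArmOutcome, control: ArmOutcome) -> CEResult:
    """Incremental cost-effectiveness of intervention vs control."""
    if intervention.perspective is not control.perspective:
        raise ValueError("outcomes computed under different perspectives")
    d_cost = intervention.cost - control.cost
    d_ly = intervention.ly - control.ly
    d_qaly = intervention.qaly - control.qaly
    dominance = Dominance.NONE
    if d_qaly > 0 and d_cost < 0:
        dominance = Dominance.INTERVENTION_DOMINANT
    elif d_qaly < 0 and d_cost > 0:
        dominance = Dominance.INTERVENTION_DOMINATED
    return CEResult(
        perspective=intervention.perspective,
        delta_cost=d_cost,
        delta_ly=d_ly,
        delta_qaly=d_qaly,
        icer_per_ly=d_cost / d_ly if d_ly != 0 else None,
        icer_per_qaly=d_cost / d_qaly if d_qaly != 0 else None,
        dominance=dominance,
    )


def net_monetary_benefit(ce: CEResult, threshold: float) -> float:
    """NMB = threshold * delta_QALY - delta_cost (PHP); positive favours the intervention."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return threshold * ce.delta_qaly - ce.delta_cost


def deterministic_results(table: ParameterTable,
                          perspective: Perspective = Perspective.HEALTHCARE,
                          ps: ParameterSet | None = None) -> tuple[ArmOutcome, ArmOutcome, CEResult]:
    """Both arms at the parameter means (or a supplied draw) plus incrementals."""
    ps = table.means() if ps is None else ps
    trast = run_arm(ps, ARM_TRASTUZUMAB, perspective)
    chemo = run_arm(ps, ARM_CHEMO, perspective)
    return trast, chemo, compute_icer(trast, chemo)


def threshold_price_search(table: ParameterTable, threshold: float,
                           perspective: Perspective = Perspective.HEALTHCARE,
                           tol: float = 1.0) -> float:
    """Treatment-course price of the trastuzumab bundle at which the
    deterministic ICER per QALY equals the threshold.

    The decision variable is the whole per-patient trastuzumab-therapy
    bundle cost for the chosen perspective (direct medical cost; plus the
    direct non-medical course cost under the societal perspective).  Found
    by root bracketing on NMB(price) to within ``tol`` PHP and verified by
    |NMB| at the root.
    """
    ps0 = table.means()
    dnmc = ps0["dnmc_tx_trast"] if perspective is Perspective.SOCIETAL else 0.0
    _, _, ce0 = deterministic_results(table, perspective, ps0)
    if ce0.delta_qaly <= 0:
        raise ValueError("threshold price undefined: no QALY gain at current parameters")

    def nmb_at(price: float) -> float:
        ps = ps0.with_values(dmc_tx_trast=price - dnmc)
        _, _, ce = deterministic_results(table, perspective, ps)
        return net_monetary_benefit(ce, threshold)

    current = ps0["dmc_tx_trast"] + dnmc
    lo, hi = 0.0, max(current * 2.0, 1e6)
    f_lo, f_hi = nmb_at(lo), nmb_at(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no cost-effective price in [0, {hi:,.0f}]: NMB has no sign change"
        )
    price = float(brentq(nmb_at, lo, hi, xtol=tol / 2))
    if abs(nmb_at(price)) > threshold * ce0.delta_qaly * 1e-6 + 1.0:
        raise RuntimeError("root verification failed: NMB not ~0 at returned price")
    return price
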