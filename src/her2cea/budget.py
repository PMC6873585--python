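"""Five-year governmental budget impact of national trastuzumab coverage.

The eligible population is the early-stage fraction of HER2-positive
cases among national breast-cancer prevalence and incidence.  Year 1
treats the whole prevalent pool plus that year's incident cases; each
later fiscal year treats a fresh incident cohort.  Treated cohorts accrue
follow-up costs in subsequent years from their (undiscounted) Markov
trace state costs, aged by years since treatment.  All streams are
undiscounted, direct-medical-cost-only by default (a governmental budget
holder); a societal variant is available behind the ``perspective`` flag.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cua import Perspective, state_cost_vector, treatment_course_cost
from .markov import ARM_CHEMO, ARM_TRASTUZUMAB, run_cohort
from .params import ParameterSet

__all__ = [
    "ArmBudgetStream",
    "BIAResult",
    "EligiblePopulation",
    "budget_stream",
    "drug_acquisition_cost",
    "eligible_population",
    "incremental_budget",
    "run_bia",
]


@dataclass(frozen=True)
class EligiblePopulation:
    """Treatable HER2-positive early-stage breast-cancer cases."""

    prevalent_cases: int
    incident_cases_per_year: int

    def __post_init__(self):
        if self.prevalent_cases < 0 or self.incident_cases_per_year < 0:
            raise ValueError("population counts must be non-negative")


def eligible_population(prevalent_bc: float, incident_bc: float,
                        her2_rate: float, early_rate: float) -> EligiblePopulation:
    """Early-stage HER2-positive counts from national totals, rounded to whole persons."""
    for r in (her2_rate, early_rate):
        if not 0 <= r <= 1:
            raise ValueError(f"rates must lie in [0,1] (got {r})")
    if prevalent_bc < 0 or incident_bc < 0:
        raise ValueError("case counts must be non-negative")
    return EligiblePopulation(
        prevalent_cases=round(prevalent_bc * her2_rate * early_rate),
        incident_cases_per_year=round(incident_bc * her2_rate * early_rate),
    )


@dataclass
class ArmBudgetStream:
    """Undiscounted fiscal-year cost stream (PHP) for one strategy."""

    arm: str
    treatment_cost: np.ndarray  # per fiscal year
    follow_up_cost: np.ndarray

    @property
    def total_cost(self) -> np.ndarray:
        return self.treatment_cost + self.follow_up_cost

    @property
    def years(self) -> int:
        return len(self.treatment_cost)


def budget_stream(ps: ParameterSet, pop: EligiblePopulation, arm: str,
                  years: int = 5,
                  perspective: Perspective = Perspective.HEALTHCARE) -> ArmBudgetStream:
    """Undiscounted cost stream of treating the eligible population.

    Fiscal year 1 treats ``prevalent + incident`` patients at the arm's
    per-course treatment cost; years 2..n each treat a new incident cohort.
    A cohort treated in year j contributes follow-up in year y > j equal to
    its size times the trace's state-cost flow at cycle ``y - j``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    cohort_sizes = np.full(years, float(pop.incident_cases_per_year))
    cohort_sizes[0] += pop.prevalent_cases

    tx_per_patient = treatment_course_cost(ps, arm, perspective)
    trace = run_cohort(ps, arm)
    state_flow = trace.occupancy @ state_cost_vector(ps, perspective)  # per patient, by cycle

    treatment = cohort_sizes * tx_per_patient
    follow_up = np.zeros(years)
    for j in range(years):  # cohort treated in fiscal year j+1
        for y in range(j + 1, years):
            age = y - j  # 1-based trace cycle in fiscal year y+1
            if age <= trace.horizon:
                follow_up[y] += cohort_sizes[j] * state_flow[age - 1]
    return ArmBudgetStream(arm=arm, treatment_cost=treatment, follow_up_cost=follow_up)


def incremental_budget(trast: ArmBudgetStream, chemo: ArmBudgetStream) -> np.ndarray:
    """Element-wise trastuzumab-minus-chemotherapy total cost stream."""
    if trast.years != chemo.years:
        raise ValueError("budget streams cover different numbers of years")
    return trast.total_cost - chemo.total_cost


def drug_acquisition_cost(price_per_course: float, n_patients: float) -> float:
    """Total drug-only acquisition outlay: price times patients treated."""
    if price_per_course < 0 or n_patients < 0:
        raise ValueError("inputs must be non-negative")
    return price_per_course * n_patients


@dataclass
class BIAResult:
    """Per-fiscal-year streams for both strategies plus the incremental."""

    trastuzumab: ArmBudgetStream
    chemotherapy: ArmBudgetStream
    population: EligiblePopulation

    @property
    def incremental(self) -> np.ndarray:
        return incremental_budget(self.trastuzumab, self.chemotherapy)

    def to_frame(self) -> pd.DataFrame:
        years = np.arange(1, self.trastuzumab.years + 1)
        return pd.DataFrame({
            "fiscal_year": years,
            "trastuzumab_treatment": self.trastuzumab.treatment_cost,
            "trastuzumab_follow_up": self.trastuzumab.follow_up_cost,
            "trastuzumab_total": self.trastuzumab.total_cost,
            "chemotherapy_treatment": self.chemotherapy.treatment_cost,
            "chemotherapy_follow_up": self.chemotherapy.follow_up_cost,
            "chemotherapy_total": self.chemotherapy.total_cost,
            "incremental": self.incremental,
        })


def run_bia(ps: ParameterSet, years: int = 5,
            perspective: Perspective = Perspective.HEALTHCARE,
            pop: EligiblePopulation | None = None) -> BIAResult:
    """Budget impact from a parameter set's own epidemiology inputs."""
    if pop is None:
        pop = eligible_population(
            ps["prevalent_bc"], ps["incident_bc"], ps["her2_rate"], ps["early_rate"],
        )
    return BIAResult(
        trastuzumab=budget_stream(ps, pop, ARM_TRASTUZUMAB, years, perspective),
        chemotherapy=budget_stream(ps, pop, ARM_CHEMO, years, perspective),
        population=pop,
    )
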