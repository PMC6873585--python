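"""Markov cohort engine: transition matrices and cohort traces.

The published model has five health states — disease-free survival (DFS),
congestive heart failure (CHF), local recurrence, distant metastasis, and
death — over 1-year cycles.  Because recurrence and metastasis carry
different costs in the first year than afterwards, the engine expands each
into a one-cycle tunnel sub-state (``REC_Y1``/``MET_Y1``) followed by a
persistent sub-state (``REC_LATER``/``MET_LATER``), giving seven states.

The treatment effect of trastuzumab enters as hazard ratios on the DFS
exits to recurrence/metastasis (pooled DFS hazard ratio) and to death
(pooled OS hazard ratio) during the efficacy window, and as a risk ratio
multiplying the CHF entry probability during the treatment year.  CHF is
occupied for a single cycle (cardiotoxicity is modelled as a once-only,
mostly reversible event); its residual mass returns to DFS.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .params import ParameterSet

__all__ = [
    "ARMS",
    "ARM_CHEMO",
    "ARM_TRASTUZUMAB",
    "CohortTrace",
    "HealthState",
    "InfeasibleTransitionError",
    "N_STATES",
    "apply_hazard_ratio",
    "build_transition_matrix",
    "run_cohort",
]

ARM_TRASTUZUMAB = "trastuzumab"
ARM_CHEMO = "chemotherapy"
ARMS = (ARM_TRASTUZUMAB, ARM_CHEMO)


class HealthState(IntEnum):
    DFS = 0
    CHF = 1
    REC_Y1 = 2
    REC_LATER = 3
    MET_Y1 = 4
    MET_LATER = 5
    DEATH = 6


N_STATES = len(HealthState)

#: states contributing life-years
ALIVE = np.array([s != HealthState.DEATH for s in HealthState])


class InfeasibleTransitionError(ValueError):
    """A state's exit probabilities sum beyond 1."""

    def __init__(self, state: HealthState, total: float):
        self.state = state
        super().__init__(
            f"exit probabilities from state {state.name} sum to {total:.6g} > 1"
        )


def apply_hazard_ratio(p: float, hr: float, mode: str = "power") -> float:
    """Apply a hazard ratio to an annual transition probability.

    Default is the constant-hazard conversion ``1 - (1-p)^hr``, the standard
    mapping for per-cycle probabilities under proportional hazards;
    ``mode="multiply"`` applies the ratio directly on the probability scale.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"probability out of range: {p}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be positive: {hr}")
    if p == 1 and hr != 1:
        raise ValueError("cannot rescale a certain event (p = 1) by a hazard ratio")
    if mode == "multiply":
        out = p * hr
        if out > 1:
            raise ValueError(f"p * hr = {out:.6g} exceeds 1")
        return out
    return 1.0 - (1.0 - p) ** hr


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")


def build_transition_matrix(ps: ParameterSet, arm: str, cycle: int) -> np.ndarray:
    """Row-stochastic 7x7 transition matrix for one arm and 1-based cycle.

    DFS exits: CHF (treatment year only by default, risk-ratio-scaled in the
    trastuzumab arm), recurrence, metastasis, death — the latter three under
    the arm's hazard ratios while efficacy lasts; residual stays in DFS.
    CHF exits to recurrence/metastasis/death with residual back to DFS.
    Recurrence states exit to metastasis or death, residual to REC_LATER;
    metastasis states exit to death, residual to MET_LATER; death absorbs.
    """
    _check_arm(arm)
    st = ps.settings
    if not 1 <= cycle <= st.horizon_cycles:
        raise ValueError(f"cycle {cycle} outside 1..{st.horizon_cycles}")
    on_treatment_effect = arm == ARM_TRASTUZUMAB and cycle <= st.efficacy_duration_years

    chf_open = cycle == 1 if st.chf_entry == "first_cycle" else True
    p_chf = ps["tp_dfs_chf"] if chf_open else 0.0
    if chf_open and arm == ARM_TRASTUZUMAB and cycle == 1:
        # risk ratio for the treatment-related cardiotoxic event, applied
        # multiplicatively on the (small) baseline probability
        p_chf = p_chf * ps["rr_chf"]
    if on_treatment_effect:
        p_rec = apply_hazard_ratio(ps["tp_dfs_rec"], ps["hr_dfs"], st.hr_mode)
        p_met = apply_hazard_ratio(ps["tp_dfs_met"], ps["hr_dfs"], st.hr_mode)
        p_death = apply_hazard_ratio(ps["tp_dfs_death"], ps["hr_os"], st.hr_mode)
    else:
        p_rec, p_met, p_death = ps["tp_dfs_rec"], ps["tp_dfs_met"], ps["tp_dfs_death"]

    m = np.zeros((N_STATES, N_STATES))
    S = HealthState

    exits = p_chf + p_rec + p_met + p_death
    if exits > 1:
        raise InfeasibleTransitionError(S.DFS, exits)
    m[S.DFS, S.CHF] = p_chf
    m[S.DFS, S.REC_Y1] = p_rec
    m[S.DFS, S.MET_Y1] = p_met
    m[S.DFS, S.DEATH] = p_death
    m[S.DFS, S.DFS] = 1.0 - exits

    chf_exits = ps["tp_chf_rec"] + ps["tp_chf_met"] + ps["tp_chf_death"]
    if chf_exits > 1:
        raise InfeasibleTransitionError(S.CHF, chf_exits)
    m[S.CHF, S.REC_Y1] = ps["tp_chf_rec"]
    m[S.CHF, S.MET_Y1] = ps["tp_chf_met"]
    m[S.CHF, S.DEATH] = ps["tp_chf_death"]
    m[S.CHF, S.DFS] = 1.0 - chf_exits  # CHF is mostly reversible: residual returns to DFS

    rec_exits = ps["tp_rec_met"] + ps["tp_rec_death"]
    if rec_exits > 1:
        raise InfeasibleTransitionError(S.REC_Y1, rec_exits)
    for s in (S.REC_Y1, S.REC_LATER):
        m[s, S.MET_Y1] = ps["tp_rec_met"]
        m[s, S.DEATH] = ps["tp_rec_death"]
        m[s, S.REC_LATER] = 1.0 - rec_exits

    if ps["tp_met_death"] > 1:
        raise InfeasibleTransitionError(S.MET_Y1, ps["tp_met_death"])
    for s in (S.MET_Y1, S.MET_LATER):
        m[s, S.DEATH] = ps["tp_met_death"]
        m[s, S.MET_LATER] = 1.0 - ps["tp_met_death"]

    m[S.DEATH, S.DEATH] = 1.0
    return m


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one arm's cohort.

    ``occupancy[t-1]`` is the state distribution at the *end* of 1-based
    cycle ``t``; the cohort enters the model with unit mass in DFS.
    """

    occupancy: np.ndarray  # (horizon_cycles, N_STATES)
    arm: str

    def __post_init__(self):
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (cycles, {N_STATES})")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("cohort mass not conserved")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError("occupancy outside [0, 1]")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=[s.name for s in HealthState])
        df.insert(0, "cycle", np.arange(1, self.horizon + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_cohort(ps: ParameterSet, arm: str) -> CohortTrace:
    """Simulate the cohort over the horizon; returns one row per cycle.

    The transition matrix is constant within regimes (treatment year, the
    rest of the efficacy window, post-efficacy), so matrices are cached by
    regime rather than rebuilt every cycle.
    """
    _check_arm(arm)
    horizon = ps.settings.horizon_cycles
    cache: dict[tuple, np.ndarray] = {}

    def regime(cycle: int) -> tuple:
        return (
            cycle == 1 if ps.settings.chf_entry == "first_cycle" else True,
            arm == ARM_TRASTUZUMAB and cycle == 1,
            arm == ARM_TRASTUZUMAB and cycle <= ps.settings.efficacy_duration_years,
        )

    x = np.zeros(N_STATES)
    x[HealthState.DFS] = 1.0
    occ = np.empty((horizon, N_STATES))
    for t in range(1, horizon + 1):
        key = regime(t)
        if key not in cache:
            cache[key] = build_transition_matrix(ps, arm, t)
        x = x @ cache[key]
        occ[t - 1] = x
    return CohortTrace(occ, arm)
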