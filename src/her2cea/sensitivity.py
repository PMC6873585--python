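"""Probabilistic, one-way and two-way sensitivity analyses.

The PSA is a second-order Monte Carlo simulation: each replication draws
one value per parameter from its sampling distribution, runs both arms
through the Markov engine, and stores the incremental discounted cost
(both perspectives), life-years and QALYs.  Draws whose transition rows
would sum beyond 1 are rejected and redrawn; the rejection count is
reported.  CEACs are the fraction of replications with positive net
monetary benefit on a threshold grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cua import (
    Perspective,
    accumulate_outcomes,
    compute_icer,
    deterministic_results,
    net_monetary_benefit,
)
from .markov import ARM_CHEMO, ARM_TRASTUZUMAB, InfeasibleTransitionError, run_cohort
from .params import ParameterTable, sample_parameter_set

__all__ = [
    "CEACCurve",
    "PSAResult",
    "TornadoEntry",
    "ceac",
    "default_one_way_ranges",
    "one_way_sa",
    "run_psa",
    "two_way_sa",
]

DEFAULT_PSA_SEED = 2019
DEFAULT_PSA_N = 50_000
#: CEAC threshold grid: 0 to 1,000,000 PHP/QALY in steps of 10,000
DEFAULT_THRESHOLD_GRID = np.arange(0, 1_000_001, 10_000, dtype=float)


@dataclass
class PSAResult:
    """Per-replication incremental results of trastuzumab vs chemotherapy.

    ``data`` columns: delta_cost_healthcare, delta_cost_societal, delta_ly,
    delta_qaly.  Reproducible bit-exactly from (table, n, seed).
    """

    data: pd.DataFrame
    seed: int
    n_resampled: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.data)

    def delta_cost(self, perspective: Perspective = Perspective.HEALTHCARE) -> np.ndarray:
        col = ("delta_cost_healthcare" if perspective is Perspective.HEALTHCARE
               else "delta_cost_societal")
        return self.data[col].to_numpy()

    def mean_delta(self, perspective: Perspective = Perspective.HEALTHCARE) -> dict[str, float]:
        return {
            "delta_cost": float(self.delta_cost(perspective).mean()),
            "delta_ly": float(self.data["delta_ly"].mean()),
            "delta_qaly": float(self.data["delta_qaly"].mean()),
        }

    def icer_per_qaly(self, perspective: Perspective = Perspective.HEALTHCARE) -> float:
        """ICER from the PSA means (ratio of mean increments)."""
        m = self.mean_delta(perspective)
        return m["delta_cost"] / m["delta_qaly"]

    def icer_per_ly(self, perspective: Perspective = Perspective.HEALTHCARE) -> float:
        m = self.mean_delta(perspective)
        return m["delta_cost"] / m["delta_ly"]

    def prob_cost_effective(self, threshold: float,
                            perspective: Perspective = Perspective.HEALTHCARE) -> float:
        """Fraction of replications with positive NMB at the threshold."""
        nmb = threshold * self.data["delta_qaly"].to_numpy() - self.delta_cost(perspective)
        return float(np.mean(nmb > 0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def run_psa(table: ParameterTable, n: int = DEFAULT_PSA_N,
            seed: int = DEFAULT_PSA_SEED) -> PSAResult:
    """Monte Carlo PSA with ``n`` replications from one seeded generator.

    Infeasible draws (any transition row summing beyond 1 in either arm)
    are rejected and fully redrawn so that feasible draws keep their
    marginal distributions; the number of rejections is recorded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n, 4))
    resampled = 0
    i = 0
    while i < n:
        ps = sample_parameter_set(table, rng)
        try:
            traces = {arm: run_cohort(ps, arm) for arm in (ARM_TRASTUZUMAB, ARM_CHEMO)}
        except InfeasibleTransitionError:
            resampled += 1
            continue
        out = {
            (arm, persp): accumulate_outcomes(traces[arm], ps, persp)
            for arm in traces
            for persp in (Perspective.HEALTHCARE, Perspective.SOCIETAL)
        }
        hc_t = out[ARM_TRASTUZUMAB, Perspective.HEALTHCARE]
        hc_c = out[ARM_CHEMO, Perspective.HEALTHCARE]
        rows[i] = (
            hc_t.cost - hc_c.cost,
            out[ARM_TRASTUZUMAB, Perspective.SOCIETAL].cost
            - out[ARM_CHEMO, Perspective.SOCIETAL].cost,
            hc_t.ly - hc_c.ly,
            hc_t.qaly - hc_c.qaly,
        )
        i += 1
    data = pd.DataFrame(
        rows,
        columns=["delta_cost_healthcare", "delta_cost_societal", "delta_ly", "delta_qaly"],
    )
    return PSAResult(data=data, seed=seed, n_resampled=resampled)


@dataclass
class CEACCurve:
    """Probability of cost-effectiveness per strategy over a threshold grid."""

    thresholds: np.ndarray
    prob_trastuzumab: np.ndarray
    perspective: Perspective

    @property
    def prob_chemotherapy(self) -> np.ndarray:
        # two strategies: probabilities are complementary at every threshold
        return 1.0 - self.prob_trastuzumab

    def at(self, threshold: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - threshold)))
        if not np.isclose(self.thresholds[idx], threshold):
            raise ValueError(f"threshold {threshold} not on the grid")
        return float(self.prob_trastuzumab[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "prob_trastuzumab": self.prob_trastuzumab,
            "prob_chemotherapy": self.prob_chemotherapy,
        })


def ceac(psa: PSAResult, thresholds: np.ndarray | None = None,
         perspective: Perspective = Perspective.HEALTHCARE) -> CEACCurve:
    """Cost-effectiveness acceptability curve from PSA replications."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    grid = DEFAULT_THRESHOLD_GRID if thresholds is None else np.asarray(thresholds, dtype=float)
    dq = psa.data["delta_qaly"].to_numpy()
    dc = psa.delta_cost(perspective)
    probs = np.array([np.mean(lam * dq - dc > 0) for lam in grid])
    return CEACCurve(grid, probs, perspective)


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the ICER per QALY to a single input."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def default_one_way_ranges(table: ParameterTable) -> dict[str, tuple[float, float]]:
    """mean +/- 1.96 SE per sampled parameter, clipped to validity, plus the
    published ranges for the discount rate (0-6%) and efficacy duration
    (5-49 years)."""
    ranges: dict[str, tuple[float, float]] = {}
    for p in table:
        if p.se == 0 or p.distribution == "fixed":
            continue
        lo, hi = p.mean - 1.96 * p.se, p.mean + 1.96 * p.se
        if p.role in ("transition_prob", "utility"):
            lo, hi = max(lo, 1e-6), min(hi, 1 - 1e-6)
        elif p.role in ("cost_dmc", "cost_dnmc"):
            lo = max(lo, 0.0)
        else:  # relative effect
            lo = max(lo, 1e-6)
        ranges[p.name] = (lo, hi)
    ranges["discount_rate"] = (0.0, 0.06)
    ranges["efficacy_duration_years"] = (5, 49)
    return ranges


def _icer_with(table: ParameterTable, name: str, value: float,
               perspective: Perspective) -> float:
    if name in ("discount_rate", "efficacy_duration_years"):
        t = table.with_settings(**{name: value})
        ps = t.means()
        return deterministic_results(t, perspective, ps)[2].icer_per_qaly
    ps = table.means().with_values(**{name: value})
    return deterministic_results(table, perspective, ps)[2].icer_per_qaly


def one_way_sa(table: ParameterTable,
               ranges: dict[str, tuple[float, float]] | None = None,
               perspective: Perspective = Perspective.HEALTHCARE) -> list[TornadoEntry]:
    """Deterministic one-way sweep: the ICER per QALY at each parameter's low
    and high value with everything else at the means.  Sorted by span,
    largest first (tornado order)."""
    ranges = default_one_way_ranges(table) if ranges is None else ranges
    entries = []
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"invalid range for {name}: low {lo} > high {hi}")
        if name not in table.parameters and name not in ("discount_rate", "efficacy_duration_years"):
            raise ValueError(f"unknown parameter in ranges: {name}")
        entries.append(TornadoEntry(
            parameter=name, low=lo, high=hi,
            icer_low=_icer_with(table, name, lo, perspective),
            icer_high=_icer_with(table, name, hi, perspective),
        ))
    return sorted(entries, key=lambda e: e.span, reverse=True)


def two_way_sa(table: ParameterTable, hr_dfs_grid, duration_grid,
               threshold: float | None = None,
               perspective: Perspective = Perspective.HEALTHCARE) -> pd.DataFrame:
    """Cost-effective strategy (higher NMB at the threshold) over a grid of
    the DFS hazard ratio and the efficacy duration, deterministic model.

    Rows are indexed by hazard ratio, columns by duration (years); each
    cell holds the winning strategy name.
    """
    threshold = table.settings.threshold_php_per_qaly if threshold is None else threshold
    cells = {}
    for dur in duration_grid:
        t = table.with_settings(efficacy_duration_years=int(dur))
        col = []
        for hr in hr_dfs_grid:
            ps = t.means().with_values(hr_dfs=float(hr))
            _, _, ce = deterministic_results(t, perspective, ps)
            col.append(ARM_TRASTUZUMAB if net_monetary_benefit(ce, threshold) > 0 else ARM_CHEMO)
        cells[int(dur)] = col
    return pd.DataFrame(cells, index=list(hr_dfs_grid))
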