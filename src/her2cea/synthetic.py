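"""Random but structurally valid parameter tables for property testing,
plus the packaged canonical table of published inputs.

The generator builds feasibility in by construction: DFS exit
probabilities are rescaled to keep a margin below 1 even after the
risk-ratio-inflated CHF entry, beta SEs are capped below the
method-of-moments feasibility bound, and costs/utilities stay inside
their validity ranges.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .params import Parameter, ParameterTable, Settings

__all__ = ["GeneratorConfig", "generate_random_table", "perturb", "table1_fixture"]

_FIXTURE = "table1.yaml"


def fixture_path() -> Path:
    return Path(str(resources.files("her2cea.data").joinpath(_FIXTURE)))


def table1_fixture() -> ParameterTable:
    """The packaged canonical parameter table (published inputs, 2017 PHP)."""
    return ParameterTable.load(fixture_path())


@dataclass(frozen=True)
class GeneratorConfig:
    """Bounds for random table generation; defaults mirror the magnitudes of
    the published inputs (annual probabilities up to tens of percent, costs
    of thousands to about a million PHP, utilities well inside (0,1))."""

    seed: int = 0
    max_dfs_exit_total: float = 0.95  # feasibility margin of 0.05 below 1
    prob_low: float = 1e-4
    prob_high: float = 0.4
    cost_low: float = 1e3
    cost_high: float = 2e6
    utility_low: float = 0.3
    utility_high: float = 0.95
    se_ratio_low: float = 0.01
    se_ratio_high: float = 0.3
    hr_low: float = 0.3
    hr_high: float = 1.2
    rr_low: float = 1.0
    rr_high: float = 5.0

    def __post_init__(self):
        if not 0 < self.max_dfs_exit_total < 1:
            raise ValueError("max_dfs_exit_total must lie in (0,1)")
        if not 0 < self.prob_low < self.prob_high < 1:
            raise ValueError("invalid probability bounds")


def _beta_se(rng: np.random.Generator, mean: float, cfg: GeneratorConfig) -> float:
    # cap below the method-of-moments feasibility bound
    cap = 0.95 * math.sqrt(mean * (1 - mean))
    return min(mean * rng.uniform(cfg.se_ratio_low, cfg.se_ratio_high), cap)


def generate_random_table(cfg: GeneratorConfig) -> ParameterTable:
    """A random table that passes loader validation and yields conserved
    cohort traces in both arms; reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)

    def prob() -> float:
        # log-uniform keeps small annual risks well represented
        return float(np.exp(rng.uniform(np.log(cfg.prob_low), np.log(cfg.prob_high))))

    def cost() -> float:
        return float(np.exp(rng.uniform(np.log(cfg.cost_low), np.log(cfg.cost_high))))

    rr_chf = float(rng.uniform(cfg.rr_low, cfg.rr_high))
    hr_dfs = float(rng.uniform(cfg.hr_low, cfg.hr_high))
    hr_os = float(rng.uniform(cfg.hr_low, cfg.hr_high))

    dfs_exits = {k: prob() for k in ("tp_dfs_chf", "tp_dfs_rec", "tp_dfs_met", "tp_dfs_death")}
    # worst-case cycle-1 row in the intervention arm: CHF entry inflated by the
    # risk ratio, other exits possibly inflated by hr_mode="multiply" with HR > 1
    worst = (dfs_exits["tp_dfs_chf"] * rr_chf
             + max(hr_dfs, 1.0) * (dfs_exits["tp_dfs_rec"] + dfs_exits["tp_dfs_met"])
             + max(hr_os, 1.0) * dfs_exits["tp_dfs_death"])
    if worst > cfg.max_dfs_exit_total:
        scale = cfg.max_dfs_exit_total / worst
        dfs_exits = {k: v * scale for k, v in dfs_exits.items()}

    chf_exits = {k: prob() for k in ("tp_chf_rec", "tp_chf_met", "tp_chf_death")}
    total = sum(chf_exits.values())
    if total > cfg.max_dfs_exit_total:
        chf_exits = {k: v * cfg.max_dfs_exit_total / total for k, v in chf_exits.items()}

    rec_exits = {k: prob() for k in ("tp_rec_met", "tp_rec_death")}
    total = sum(rec_exits.values())
    if total > cfg.max_dfs_exit_total:
        rec_exits = {k: v * cfg.max_dfs_exit_total / total for k, v in rec_exits.items()}

    tps = {**dfs_exits, **chf_exits, **rec_exits, "tp_met_death": prob()}

    params: dict[str, Parameter] = {}
    for name, mean in tps.items():
        params[name] = Parameter(name, mean, _beta_se(rng, mean, cfg), "beta", "transition_prob")
    for name, mean in (("hr_dfs", hr_dfs), ("hr_os", hr_os), ("rr_chf", rr_chf)):
        se = mean * rng.uniform(cfg.se_ratio_low, cfg.se_ratio_high)
        params[name] = Parameter(name, mean, se, "lognormal", "relative_effect")
    for name in ("u_dfs", "u_chf", "u_rec", "u_met"):
        mean = float(rng.uniform(cfg.utility_low, cfg.utility_high))
        params[name] = Parameter(name, mean, _beta_se(rng, mean, cfg), "beta", "utility")
    cost_names = (
        "dmc_tx_trast", "dmc_tx_ct", "dmc_dfs", "dmc_chf",
        "dmc_rec_y1", "dmc_rec_later", "dmc_met_y1", "dmc_met_later",
    )
    dnmc_names = (
        "dnmc_tx_trast", "dnmc_tx_ct", "dnmc_dfs", "dnmc_chf",
        "dnmc_rec_y1", "dnmc_rec_later", "dnmc_met_y1", "dnmc_met_later",
    )
    for name in cost_names + dnmc_names:
        mean = cost()
        se = mean * rng.uniform(cfg.se_ratio_low, cfg.se_ratio_high)
        role = "cost_dmc" if name.startswith("dmc") else "cost_dnmc"
        params[name] = Parameter(name, mean, se, "gamma", role)
    params["trast_drug_cost_per_course"] = Parameter(
        "trast_drug_cost_per_course", cost(), 0.0, "fixed", "cost_dmc")
    for name, hi in (("prevalent_bc", 1e5), ("incident_bc", 5e4)):
        params[name] = Parameter(name, float(rng.integers(0, int(hi))), 0.0, "fixed", "epidemiology")
    for name in ("her2_rate", "early_rate"):
        params[name] = Parameter(name, float(rng.uniform(0.05, 0.95)), 0.0, "fixed", "epidemiology")

    settings = Settings(
        discount_rate=float(rng.uniform(0.0, 0.06)),
        horizon_cycles=int(rng.integers(5, 60)),
        efficacy_duration_years=int(rng.integers(1, 20)),
    )
    return ParameterTable(params, settings)


def perturb(table: ParameterTable, fraction: float, seed: int) -> ParameterTable:
    """Jitter each mean multiplicatively by at most ``fraction``, re-clipped
    to validity (probabilities/utilities back inside (0,1), DFS exit rows
    rescaled to keep their feasibility margin, beta SEs re-capped)."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    if fraction == 0:
        return ParameterTable(dict(table.parameters), table.settings)
    rng = np.random.default_rng(seed)
    params: dict[str, Parameter] = {}
    for name, p in table.parameters.items():
        mean = p.mean * (1.0 + rng.uniform(-fraction, fraction))
        se = p.se
        if p.role in ("transition_prob", "utility"):
            mean = float(np.clip(mean, 1e-6, 1 - 1e-6))
            if p.distribution == "beta" and se > 0:
                se = min(se, 0.95 * math.sqrt(mean * (1 - mean)))
        elif p.role in ("cost_dmc", "cost_dnmc", "epidemiology"):
            mean = max(mean, 0.0)
        else:
            mean = max(mean, 1e-6)
        params[name] = Parameter(name, mean, se, p.distribution, p.role)

    def rescale_row(names: tuple[str, ...], cap: float = 0.95) -> None:
        total = sum(params[n].mean for n in names)
        if total > cap:
            for n in names:
                p = params[n]
                mean = p.mean * cap / total
                se = min(p.se, 0.95 * math.sqrt(mean * (1 - mean))) if p.se > 0 else 0.0
                params[n] = Parameter(n, mean, se, p.distribution, p.role)

    rescale_row(("tp_chf_rec", "tp_chf_met", "tp_chf_death"))
    rescale_row(("tp_rec_met", "tp_rec_death"))

    # keep the intervention-arm cycle-1 DFS row feasible after jitter
    rr = params["rr_chf"].mean
    worst = (params["tp_dfs_chf"].mean * max(rr, 1.0)
             + max(params["hr_dfs"].mean, 1.0)
             * (params["tp_dfs_rec"].mean + params["tp_dfs_met"].mean)
             + max(params["hr_os"].mean, 1.0) * params["tp_dfs_death"].mean)
    if worst > 0.95:
        scale = 0.95 / worst
        for name in ("tp_dfs_chf", "tp_dfs_rec", "tp_dfs_met", "tp_dfs_death"):
            p = params[name]
            mean = p.mean * scale
            se = min(p.se, 0.95 * math.sqrt(mean * (1 - mean))) if p.se > 0 else 0.0
            params[name] = Parameter(name, mean, se, p.distribution, p.role)
    return ParameterTable(params, table.settings)
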