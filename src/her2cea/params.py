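"""Model parameters, their sampling distributions, and PSA draws.

Every input of the decision model — annual transition probabilities,
pooled hazard/risk ratios for the treatment effect, health-state
utilities, and 2017-PHP costs — is a :class:`Parameter` carrying a mean,
a standard error and a sampling-distribution family.  Probabilistic
sensitivity analysis converts each ``(mean, se)`` pair into a fully
specified distribution by method of moments (beta, gamma) or a
delta-method transfer to the log scale (log-normal), and draws one
independent value per parameter per Monte Carlo replication.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DistributionSpec",
    "Parameter",
    "ParameterSet",
    "ParameterTable",
    "ParameterValidationError",
    "Settings",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_point",
    "load_parameter_table",
    "sample_parameter_set",
    "REQUIRED_SYMBOLS",
]

ROLES = (
    "transition_prob",
    "relative_effect",
    "cost_dmc",
    "cost_dnmc",
    "utility",
    "epidemiology",
    "setting",
)
FAMILIES = ("beta", "gamma", "lognormal", "fixed")

#: distribution families admissible for each parameter role
ROLE_FAMILIES = {
    "transition_prob": ("beta", "fixed"),
    "utility": ("beta", "fixed"),
    "cost_dmc": ("gamma", "fixed"),
    "cost_dnmc": ("gamma", "fixed"),
    "relative_effect": ("lognormal", "fixed"),
    "epidemiology": ("fixed",),
    "setting": ("fixed",),
}

#: every symbol the model consumes; a valid table must define each exactly once
REQUIRED_SYMBOLS = (
    "tp_dfs_chf", "tp_dfs_rec", "tp_dfs_met", "tp_dfs_death",
    "tp_chf_rec", "tp_chf_met", "tp_chf_death",
    "tp_rec_met", "tp_rec_death", "tp_met_death",
    "hr_dfs", "hr_os", "rr_chf",
    "u_dfs", "u_chf", "u_rec", "u_met",
    "dmc_tx_trast", "dmc_tx_ct", "dnmc_tx_trast", "dnmc_tx_ct",
    "dmc_dfs", "dnmc_dfs", "dmc_chf", "dnmc_chf",
    "dmc_rec_y1", "dnmc_rec_y1", "dmc_rec_later", "dnmc_rec_later",
    "dmc_met_y1", "dnmc_met_y1", "dmc_met_later", "dnmc_met_later",
    "trast_drug_cost_per_course",
    "prevalent_bc", "incident_bc", "her2_rate", "early_rate",
)

#: optional symbols the loader recognises beyond the registry
OPTIONAL_SYMBOLS = ("dmc_rec_later_alt", "dnmc_rec_later_alt")


class ParameterValidationError(ValueError):
    """Raised by table validation; carries every failure, not just the first."""

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__("parameter table validation failed:\n- " + "\n- ".join(failures))


class InfeasibleMomentsError(ValueError):
    """(mean, se) pair admits no distribution of the requested family."""


@dataclass(frozen=True)
class DistributionSpec:
    """A fully parameterised sampling distribution.

    ``args`` holds ``(alpha, beta)`` for beta, ``(shape, rate)`` for gamma,
    ``(mu_log, sigma_log)`` for lognormal and ``(point,)`` for fixed.
    """

    family: str
    args: tuple[float, ...]

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family in ("beta", "gamma") and any(a <= 0 for a in self.args):
            raise ValueError(f"{self.family} shape parameters must be positive: {self.args}")
        if self.family == "lognormal" and self.args[1] <= 0:
            raise ValueError(f"lognormal sigma must be positive: {self.args}")

    def mean(self) -> float:
        """Analytic mean (lognormal: exp(mu + sigma^2/2))."""
        if self.family == "fixed":
            return self.args[0]
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "gamma":
            shape, rate = self.args
            return shape / rate
        mu, sigma = self.args
        return math.exp(mu + sigma ** 2 / 2)

    def sd(self) -> float:
        if self.family == "fixed":
            return 0.0
        if self.family == "beta":
            a, b = self.args
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            shape, rate = self.args
            return math.sqrt(shape) / rate
        mu, sigma = self.args
        return math.exp(mu + sigma ** 2 / 2) * math.sqrt(math.expm1(sigma ** 2))

    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.args[0])
        raise NotImplementedError("median only provided for lognormal specs")

    def draw(self, rng: np.random.Generator, size=None):
        if self.family == "fixed":
            return self.args[0] if size is None else np.full(size, self.args[0])
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            shape, rate = self.args
            return rng.gamma(shape, 1.0 / rate, size=size)
        mu, sigma = self.args
        return rng.lognormal(mu, sigma, size=size)


def beta_from_moments(mean: float, se: float, name: str = "") -> DistributionSpec:
    """Beta distribution matching a (mean, SE) pair by method of moments.

    ``k = mean(1-mean)/se^2 - 1``; ``alpha = mean k``; ``beta = (1-mean) k``.
    A zero SE degenerates to a point mass.
    """
    if not 0 < mean < 1:
        raise InfeasibleMomentsError(f"beta mean must lie in (0,1): {name or mean}")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        return DistributionSpec("fixed", (mean,))
    if se ** 2 >= mean * (1 - mean):
        raise InfeasibleMomentsError(
            f"infeasible beta moments for {name or 'parameter'}: "
            f"se^2={se**2:.6g} >= mean(1-mean)={mean*(1-mean):.6g}"
        )
    k = mean * (1 - mean) / se ** 2 - 1
    return DistributionSpec("beta", (mean * k, (1 - mean) * k))


def gamma_from_moments(mean: float, se: float, name: str = "") -> DistributionSpec:
    """Gamma distribution matching a (mean, SE) pair: shape = mean^2/se^2, rate = mean/se^2."""
    if mean <= 0:
        raise InfeasibleMomentsError(f"gamma mean must be positive: {name or mean}")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        return DistributionSpec("fixed", (mean,))
    return DistributionSpec("gamma", (mean ** 2 / se ** 2, mean / se ** 2))


def lognormal_from_point(ratio: float, se: float, moment_matched: bool = False) -> DistributionSpec:
    """Log-normal for a hazard/risk ratio reported as point (SE) on the ratio scale.

    Default (delta method): ``mu = ln(ratio)``, ``sigma = se/ratio``, so the
    sampling *median* equals the point estimate.  With ``moment_matched=True``
    the analytic mean is matched instead: ``mu = ln(ratio) - sigma^2/2`` with
    ``sigma^2 = ln(1 + (se/ratio)^2)``.
    """
    if ratio <= 0:
        raise InfeasibleMomentsError(f"ratio must be positive: {ratio}")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        return DistributionSpec("fixed", (ratio,))
    if moment_matched:
        sigma2 = math.log1p((se / ratio) ** 2)
        return DistributionSpec("lognormal", (math.log(ratio) - sigma2 / 2, math.sqrt(sigma2)))
    return DistributionSpec("lognormal", (math.log(ratio), se / ratio))


@dataclass(frozen=True)
class Parameter:
    """One named model input with its PSA sampling distribution."""

    name: str
    mean: float
    se: float
    distribution: str
    role: str

    def validate(self) -> list[str]:
        bad = []
        if self.role not in ROLES:
            bad.append(f"{self.name}: unknown role {self.role!r}")
        if self.distribution not in FAMILIES:
            bad.append(f"{self.name}: unknown distribution family {self.distribution!r}")
            return bad
        if self.se < 0:
            bad.append(f"{self.name}: se must be >= 0 (got {self.se})")
        if self.role in ("transition_prob", "utility") and not 0 <= self.mean <= 1:
            bad.append(f"{self.name}: {self.role} mean must lie in [0,1] (got {self.mean})")
        if self.role in ("cost_dmc", "cost_dnmc", "epidemiology") and self.mean < 0:
            bad.append(f"{self.name}: {self.role} mean must be >= 0 (got {self.mean})")
        if self.role == "relative_effect" and self.mean <= 0:
            bad.append(f"{self.name}: ratio must be > 0 (got {self.mean})")
        if self.role in ROLE_FAMILIES and self.distribution not in ROLE_FAMILIES[self.role]:
            bad.append(
                f"{self.name}: distribution {self.distribution!r} inconsistent with role "
                f"{self.role!r} (expected one of {ROLE_FAMILIES[self.role]})"
            )
        if not bad and self.distribution == "beta" and self.se > 0:
            try:
                beta_from_moments(self.mean, self.se, self.name)
            except InfeasibleMomentsError as err:
                bad.append(str(err))
        return bad

    def spec(self, lognormal_mode: str = "median") -> DistributionSpec:
        """The sampling distribution implied by (mean, se, family)."""
        if self.se == 0 or self.distribution == "fixed":
            return DistributionSpec("fixed", (self.mean,))
        if self.distribution == "beta":
            return beta_from_moments(self.mean, self.se, self.name)
        if self.distribution == "gamma":
            return gamma_from_moments(self.mean, self.se, self.name)
        return lognormal_from_point(self.mean, self.se, moment_matched=(lognormal_mode == "moment"))


@dataclass
class Settings:
    """Run settings and structural flags of the model.

    The first block is the published analysis configuration; the second
    exposes the structural choices the publication leaves open (see
    docs/methods.md) so they can be varied in sensitivity analyses.
    """

    discount_rate: float = 0.035
    horizon_cycles: int = 49
    efficacy_duration_years: int = 11
    threshold_php_per_qaly: float = 120_000.0
    start_age: int = 50

    # structural flags (defaults are the package's reference configuration)
    hr_mode: str = "power"  # "power": p' = 1-(1-p)^HR; "multiply": p' = p*HR
    chf_entry: str = "first_cycle"  # or "every_cycle"
    recurrence_later_costs: str = "primary"  # or "alternate" (second published row)
    half_cycle: bool = False
    discount_from_first_cycle: bool = True  # factor (1+r)^-(t-1); False: (1+r)^-t
    lognormal_mode: str = "median"  # or "moment"

    def validate(self) -> list[str]:
        bad = []
        if self.discount_rate < 0:
            bad.append(f"discount_rate must be >= 0 (got {self.discount_rate})")
        for name in ("horizon_cycles", "efficacy_duration_years", "threshold_php_per_qaly", "start_age"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be positive (got {getattr(self, name)})")
        if self.hr_mode not in ("power", "multiply"):
            bad.append(f"hr_mode must be 'power' or 'multiply' (got {self.hr_mode!r})")
        if self.chf_entry not in ("first_cycle", "every_cycle"):
            bad.append(f"chf_entry must be 'first_cycle' or 'every_cycle' (got {self.chf_entry!r})")
        if self.recurrence_later_costs not in ("primary", "alternate"):
            bad.append(f"recurrence_later_costs must be 'primary' or 'alternate'")
        if self.lognormal_mode not in ("median", "moment"):
            bad.append(f"lognormal_mode must be 'median' or 'moment'")
        return bad


@dataclass(frozen=True)
class ParameterSet:
    """One realised numeric value per parameter (a PSA draw, or the means)."""

    values: Mapping[str, float]
    settings: Settings

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float | None = None):
        return self.values.get(name, default)

    def with_values(self, **overrides: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(overrides)
        return ParameterSet(vals, self.settings)

    def with_settings(self, **overrides) -> "ParameterSet":
        return ParameterSet(self.values, replace(self.settings, **overrides))


@dataclass
class ParameterTable:
    """The full set of named parameters plus run settings."""

    parameters: dict[str, Parameter]
    settings: Settings = field(default_factory=Settings)

    def __post_init__(self):
        self.validate()

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self.parameters.values())

    def __getitem__(self, name: str) -> Parameter:
        return self.parameters[name]

    def validate(self) -> None:
        failures: list[str] = []
        for sym in REQUIRED_SYMBOLS:
            if sym not in self.parameters:
                failures.append(f"missing required parameter {sym}")
        for p in self.parameters.values():
            failures.extend(p.validate())
        failures.extend(self.settings.validate())
        if failures:
            raise ParameterValidationError(failures)

    def means(self) -> ParameterSet:
        return ParameterSet({n: p.mean for n, p in self.parameters.items()}, self.settings)

    def with_settings(self, **overrides) -> "ParameterTable":
        return ParameterTable(dict(self.parameters), replace(self.settings, **overrides))

    def with_parameter(self, name: str, **overrides) -> "ParameterTable":
        params = dict(self.parameters)
        params[name] = replace(params[name], **overrides)
        return ParameterTable(params, self.settings)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.name, p.mean, p.se, p.distribution, p.role) for p in self],
            columns=["name", "mean", "se", "distribution", "role"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save(self, path: str | Path) -> None:
        doc = {
            "settings": {f.name: getattr(self.settings, f.name) for f in fields(Settings)},
            "parameters": [
                {"name": p.name, "mean": p.mean, "se": p.se,
                 "distribution": p.distribution, "role": p.role}
                for p in self
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_dict(cls, doc: dict) -> "ParameterTable":
        failures: list[str] = []
        raw = doc.get("parameters")
        if not isinstance(raw, list):
            raise ParameterValidationError(["file has no 'parameters' list"])
        params: dict[str, Parameter] = {}
        for entry in raw:
            try:
                p = Parameter(
                    name=str(entry["name"]),
                    mean=float(entry["mean"]),
                    se=float(entry.get("se", 0.0)),
                    distribution=str(entry.get("distribution", "fixed")),
                    role=str(entry.get("role", "setting")),
                )
            except (KeyError, TypeError, ValueError) as err:
                failures.append(f"malformed parameter entry {entry!r}: {err}")
                continue
            if p.name in params:
                failures.append(f"duplicate parameter {p.name}")
            params[p.name] = p
        known = {f.name for f in fields(Settings)}
        sdoc = doc.get("settings") or {}
        unknown = set(sdoc) - known
        if unknown:
            failures.append(f"unknown settings: {sorted(unknown)}")
        settings = Settings(**{k: v for k, v in sdoc.items() if k in known})
        if failures:
            raise ParameterValidationError(failures)
        return cls(params, settings)

    @classmethod
    def load(cls, path: str | Path) -> "ParameterTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ParameterValidationError([f"{path}: not a mapping"])
        return cls.from_dict(doc)


def load_parameter_table(path: str | Path) -> ParameterTable:
    """Load and validate a parameter file (YAML schema; see the packaged fixture)."""
    return ParameterTable.load(path)


def sample_parameter_set(table: ParameterTable, rng: np.random.Generator) -> ParameterSet:
    """One independent draw per parameter from its sampling distribution.

    Zero-SE and fixed parameters pass through unchanged, so an all-fixed
    table makes this the identity on the means.  Draw order is the table's
    parameter order: the same seeded generator reproduces draws bit-exactly.
    """
    mode = table.settings.lognormal_mode
    values = {name: p.spec(mode).draw(rng) for name, p in table.parameters.items()}
    return ParameterSet(values, table.settings)
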