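"""Simulation configuration: cohort parameters, coefficient tables, scenarios.

The data-generating mechanism mimics an observational surgical cohort split
into two prognostic subsets of unequal size (a quarter vs three quarters of
patients), where treatment uptake differs sharply between subsets (~80% vs
~40% treated) and a treatment benefit may be confined to the smaller subset.
Covariate effects on treatment allocation and on the outcome hazard are
"strong" (log 2), "moderate" (log 1.3) or absent (0).
"""
from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

COVARIATES: tuple[str, ...] = tuple(f"X{j}" for j in range(1, 11))
SUBSETS: tuple[int, int] = (1, 2)

STRONG: float = math.log(2.0)
MODERATE: float = math.log(1.3)
ABSENT: float = 0.0

#: Covariate effects on treatment allocation (log-odds scale), by subset.
#: X4 and X9 are the only covariates whose effect differs between subsets.
DEFAULT_TREATMENT_COEFFICIENTS: dict[tuple[str, int], float] = {
    ("X1", 1): MODERATE, ("X1", 2): MODERATE,
    ("X2", 1): MODERATE, ("X2", 2): MODERATE,
    ("X3", 1): ABSENT, ("X3", 2): ABSENT,
    ("X4", 1): STRONG, ("X4", 2): ABSENT,
    ("X5", 1): MODERATE, ("X5", 2): MODERATE,
    ("X6", 1): ABSENT, ("X6", 2): ABSENT,
    ("X7", 1): STRONG, ("X7", 2): STRONG,
    ("X8", 1): MODERATE, ("X8", 2): MODERATE,
    ("X9", 1): ABSENT, ("X9", 2): STRONG,
    ("X10", 1): STRONG, ("X10", 2): STRONG,
}

#: Covariate effects on the outcome hazard (log-hazard scale), common to
#: both subsets.
DEFAULT_OUTCOME_COEFFICIENTS: dict[str, float] = {
    "X1": ABSENT, "X2": MODERATE, "X3": ABSENT, "X4": STRONG,
    "X5": MODERATE, "X6": STRONG, "X7": MODERATE, "X8": STRONG,
    "X9": MODERATE, "X10": STRONG,
}


@dataclass(frozen=True)
class Scenario:
    """Conditional treatment effects (log-HR scale) per subset."""

    name: str
    theta_s1: float
    theta_s2: float

    @property
    def interaction_present(self) -> bool:
        return self.theta_s1 != self.theta_s2

    def theta(self, subset: int) -> float:
        return self.theta_s1 if subset == 1 else self.theta_s2

    @staticmethod
    def sc1() -> "Scenario":
        """Treatment works only in the smaller subset."""
        return Scenario("Sc1", -0.7, 0.0)

    @staticmethod
    def sc2(eps: float) -> "Scenario":
        """Subset-1 effect swept over [-2, 0]; none in subset 2."""
        if not -2.0 <= eps <= 0.0:
            raise ValueError(f"Sc2 effect must lie in [-2, 0], got {eps}")
        return Scenario("Sc2", eps, 0.0)

    @staticmethod
    def sc3(eps: float) -> "Scenario":
        """Homogeneous treatment effect (no interaction)."""
        return Scenario("Sc3", eps, eps)

    @staticmethod
    def sc4() -> "Scenario":
        """Global null: no treatment effect anywhere."""
        return Scenario("Sc4", 0.0, 0.0)


@dataclass(frozen=True)
class UnmeasuredConfounder:
    """An extra covariate U affecting both treatment and outcome, hidden
    from every PS model.

    U is standard normal, correlated with an observed anchor covariate
    (``rho`` in [0, 1]); ``strength`` enters both the treatment log-odds
    and the outcome log-hazard.
    """

    strength: float
    correlation: float
    anchor: str = "X2"

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation <= 1.0:
            raise ValueError(
                f"confounder correlation must lie in [0, 1], got {self.correlation}"
            )
        if self.anchor not in ("X1", "X2"):
            raise ValueError("anchor must be a continuous covariate (X1 or X2)")


class ConfigError(ValueError):
    """Invalid or unparseable simulation configuration."""


@dataclass
class SimulationConfig:
    """Every knob of the data-generating mechanism.

    Defaults reproduce the reference study conditions: n=3000 patients,
    p(S=1)=0.25, treatment-model intercepts 0.3 / -1.9 (giving ~80% / ~40%
    treated), baseline hazard 0.005, uniform censoring on [1, 150] with an
    administrative cut at 60, and subset prognostic effect log 2.
    """

    n: int = 3000
    p_s1: float = 0.25
    beta0_s1: float = 0.3
    beta0_s2: float = -1.9
    beta_treat: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_COEFFICIENTS))
    alpha_out: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_COEFFICIENTS))
    alpha_s: float = STRONG
    theta_s1: float = 0.0
    theta_s2: float = 0.0
    lambda0: float = 0.005
    censor_low: float = 1.0
    censor_high: float = 150.0
    admin_cutoff: float = 60.0
    seed: int = 20231031
    bootstrap_resamples: int = 200
    confounder: UnmeasuredConfounder | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError(f"cohort size n must be positive, got {self.n}")
        if not 0.0 <= self.p_s1 <= 1.0:
            raise ConfigError(f"p_s1 must lie in [0, 1], got {self.p_s1}")
        if self.lambda0 <= 0:
            raise ConfigError(f"lambda0 must be positive, got {self.lambda0}")
        if not 0 < self.censor_low < self.censor_high:
            raise ConfigError(
                "censoring bounds must satisfy 0 < censor_low < censor_high, "
                f"got ({self.censor_low}, {self.censor_high})")
        if self.admin_cutoff <= 0:
            raise ConfigError(
                f"admin_cutoff must be positive, got {self.admin_cutoff}")
        self.beta_treat = dict(self.beta_treat)
        self.alpha_out = dict(self.alpha_out)
        missing_t = [(c, s) for c in COVARIATES for s in SUBSETS
                     if (c, s) not in self.beta_treat]
        if missing_t:
            raise ConfigError(
                f"beta_treat must cover X1-X10 for both subsets; missing {missing_t}")
        missing_o = [c for c in COVARIATES if c not in self.alpha_out]
        if missing_o:
            raise ConfigError(f"alpha_out must cover X1-X10; missing {missing_o}")

    @property
    def default_scenario(self) -> Scenario:
        return Scenario("custom", self.theta_s1, self.theta_s2)

    def with_confounder(self, confounder: UnmeasuredConfounder) -> "SimulationConfig":
        return replace(self, confounder=confounder)


# ---------------------------------------------------------------------------
# Config-file parsing (structured YAML mirroring SimulationConfig fields)

_SCALAR_KEYS = {
    "n": int, "p_s1": float, "beta0_s1": float, "beta0_s2": float,
    "alpha_s": float, "theta_s1": float, "theta_s2": float,
    "lambda0": float, "censor_low": float, "censor_high": float,
    "admin_cutoff": float, "seed": int, "bootstrap_resamples": int,
}
_TABLE_KEYS = ("beta_treat", "alpha_out", "confounder")
_ALL_KEYS = tuple(_SCALAR_KEYS) + _TABLE_KEYS


def _unknown_key_error(key: str) -> ConfigError:
    close = difflib.get_close_matches(key, _ALL_KEYS, n=1)
    hint = f"; did you mean {close[0]!r}?" if close else ""
    return ConfigError(f"unknown configuration key {key!r}{hint}")


def validate_config(raw: str) -> SimulationConfig:
    """Parse a YAML configuration document into a :class:`SimulationConfig`.

    An empty document yields all defaults. Unknown keys are rejected (with a
    nearest-key suggestion) rather than silently ignored; out-of-range values
    raise :class:`ConfigError`.
    """
    try:
        data = yaml.safe_load(raw)
    except yaml.YAMLError as exc:  # pragma: no cover - passthrough
        raise ConfigError(f"unparseable configuration: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping of key: value pairs")

    kwargs: dict = {}
    for key, value in data.items():
        if key in _SCALAR_KEYS:
            try:
                kwargs[key] = _SCALAR_KEYS[key](value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"key {key!r}: expected a number, got {value!r}") from exc
        elif key == "beta_treat":
            kwargs[key] = _parse_treatment_table(value)
        elif key == "alpha_out":
            kwargs[key] = _parse_outcome_table(value)
        elif key == "confounder":
            if not isinstance(value, dict):
                raise ConfigError("confounder must be a mapping")
            kwargs[key] = UnmeasuredConfounder(**value)
        else:
            raise _unknown_key_error(str(key))
    try:
        return SimulationConfig(**kwargs)
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def _parse_treatment_table(value) -> dict[tuple[str, int], float]:
    if not isinstance(value, dict):
        raise ConfigError("beta_treat must be a mapping covariate -> {subset: value}")
    table = dict(DEFAULT_TREATMENT_COEFFICIENTS)
    for cov, per_subset in value.items():
        if cov not in COVARIATES:
            raise ConfigError(f"beta_treat: unknown covariate {cov!r}")
        if not isinstance(per_subset, dict):
            raise ConfigError(
                f"beta_treat[{cov}] must map subset (1/2) to a coefficient")
        for s, coef in per_subset.items():
            if int(s) not in SUBSETS:
                raise ConfigError(f"beta_treat[{cov}]: subset must be 1 or 2, got {s}")
            table[(cov, int(s))] = float(coef)
    return table


def _parse_outcome_table(value) -> dict[str, float]:
    if not isinstance(value, dict):
        raise ConfigError("alpha_out must be a mapping covariate -> value")
    table = dict(DEFAULT_OUTCOME_COEFFICIENTS)
    for cov, coef in value.items():
        if cov not in COVARIATES:
            raise ConfigError(f"alpha_out: unknown covariate {cov!r}")
        table[cov] = float(coef)
    return table


def dump_config(config: SimulationConfig) -> str:
    """Serialize a config back to YAML (round-trips through validate_config)."""
    data: dict = {k: getattr(config, k) for k in _SCALAR_KEYS}
    data["beta_treat"] = {
        cov: {s: config.beta_treat[(cov, s)] for s in SUBSETS} for cov in COVARIATES}
    data["alpha_out"] = {cov: config.alpha_out[cov] for cov in COVARIATES}
    if config.confounder is not None:
        data["confounder"] = {
            "strength": config.confounder.strength,
            "correlation": config.confounder.correlation,
            "anchor": config.confounder.anchor,
        }
    return yaml.safe_dump(data, sort_keys=False)
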