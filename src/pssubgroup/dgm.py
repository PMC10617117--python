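"""Data-generating mechanism: synthetic cohorts and counterfactual truths.

Cohorts carry ten baseline covariates (X1, X2 standard normal; X3-X10
Bernoulli(0.5)), a two-level subset label S (S=1 the smaller subset),
a treatment indicator Z drawn from a subset-specific logistic model, and a
right-censored exponential survival outcome. Large survival times indicate
improved outcomes; patients are censored by a uniform[1, 150] random
censoring time or administratively at 60.

Randomness is organised in named substreams spawned from one root seed so
that scenarios sharing a seed share covariates, subset labels, treatment
assignment and censoring draws, differing only through the hazard.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy.special import expit

from .config import COVARIATES, Scenario, SimulationConfig

CONFOUNDER_NAME = "U"

#: substream order consumed by generate_cohort (documented contract)
_SUBSTREAMS = ("covariates", "subset", "treatment", "event", "censoring")


class GenerationError(RuntimeError):
    """Cohort generation produced invalid values (non-finite hazards etc.)."""


@dataclass
class Cohort:
    """One generated dataset.

    ``covariates`` holds X1..X10 (plus the hidden confounder U when the
    config requests one); ``subset`` is coded 1/2 with 1 the smaller subset.
    """

    covariates: pd.DataFrame
    subset: np.ndarray
    treatment: np.ndarray
    time: np.ndarray
    event: np.ndarray

    @property
    def n(self) -> int:
        return len(self.subset)

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df["S"] = self.subset
        df["Z"] = self.treatment
        df["time"] = self.time
        df["event"] = self.event
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "Cohort":
        cov_cols = [c for c in df.columns if c in COVARIATES or c == CONFOUNDER_NAME]
        return Cohort(
            covariates=df[cov_cols].reset_index(drop=True),
            subset=df["S"].to_numpy(dtype=int),
            treatment=df["Z"].to_numpy(dtype=int),
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(dtype=int),
        )


def _resolve_streams(rng_state) -> dict[str, np.random.Generator]:
    if isinstance(rng_state, np.random.SeedSequence):
        ss = rng_state
    else:
        ss = np.random.SeedSequence(rng_state)
    children = ss.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_SUBSTREAMS, children)}


def _draw_covariates(config: SimulationConfig, n: int,
                     rng: np.random.Generator) -> pd.DataFrame:
    cols = {
        "X1": rng.normal(size=n),
        "X2": rng.normal(size=n),
    }
    for j in range(3, 11):
        cols[f"X{j}"] = rng.integers(0, 2, size=n).astype(float)
    if config.confounder is not None:
        # U | anchor: correlated standard normal; drawn last so that a
        # null-strength confounder leaves all other draws untouched.
        rho = config.confounder.correlation
        eps = rng.normal(size=n)
        cols[CONFOUNDER_NAME] = rho * cols[config.confounder.anchor] + \
            np.sqrt(max(0.0, 1.0 - rho ** 2)) * eps
    return pd.DataFrame(cols)


def _treatment_logit(config: SimulationConfig, X: pd.DataFrame,
                     subset: np.ndarray) -> np.ndarray:
    is1 = subset == 1
    eta = np.where(is1, config.beta0_s1, config.beta0_s2).astype(float)
    for cov in COVARIATES:
        b = np.where(is1, config.beta_treat[(cov, 1)], config.beta_treat[(cov, 2)])
        eta += b * X[cov].to_numpy()
    if config.confounder is not None:
        eta += config.confounder.strength * X[CONFOUNDER_NAME].to_numpy()
    return eta


def _outcome_log_hazard(config: SimulationConfig, X: pd.DataFrame,
                        subset: np.ndarray) -> np.ndarray:
    """Log-hazard linear predictor excluding treatment: log lambda0 +
    alpha_S 1[S=1] + sum_j alpha_j x_j (+ confounder)."""
    lp = np.log(config.lambda0) + config.alpha_s * (subset == 1).astype(float)
    for cov in COVARIATES:
        lp = lp + config.alpha_out[cov] * X[cov].to_numpy()
    if config.confounder is not None:
        lp = lp + config.confounder.strength * X[CONFOUNDER_NAME].to_numpy()
    return lp


def generate_cohort(config: SimulationConfig, scenario: Scenario | None = None,
                    rng_state=None) -> Cohort:
    """Generate one cohort of exactly ``config.n`` patients.

    ``rng_state`` may be an integer seed or a ``numpy.random.SeedSequence``;
    it defaults to ``config.seed``. Identical (config, scenario, rng_state)
    triples yield bit-identical cohorts.
    """
    scenario = scenario or config.default_scenario
    streams = _resolve_streams(config.seed if rng_state is None else rng_state)
    n = config.n

    X = _draw_covariates(config, n, streams["covariates"])
    subset = np.where(streams["subset"].random(n) < config.p_s1, 1, 2)

    eta = _treatment_logit(config, X, subset)
    if not np.all(np.isfinite(eta)):
        raise GenerationError("non-finite treatment linear predictor")
    treatment = (streams["treatment"].random(n) < expit(eta)).astype(int)

    theta = np.where(subset == 1, scenario.theta_s1, scenario.theta_s2)
    log_hazard = _outcome_log_hazard(config, X, subset) + theta * treatment
    if not np.all(np.isfinite(log_hazard)):
        raise GenerationError("non-finite outcome linear predictor")
    latent = streams["event"].exponential(scale=np.exp(-log_hazard))
    censor = streams["censoring"].uniform(config.censor_low, config.censor_high, n)

    cap = np.minimum(censor, config.admin_cutoff)
    time = np.minimum(latent, cap)
    event = (latent <= cap).astype(int)
    return Cohort(X, subset, treatment, time, event)


def apply_censoring(latent_time: float, censor_time: float,
                    admin_cutoff: float) -> tuple[float, int]:
    """Observed follow-up and event status for one patient.

    The event is observed iff the latent event time precedes both the random
    censoring time and the administrative cutoff.
    """
    if latent_time <= 0 or censor_time <= 0 or admin_cutoff <= 0:
        raise ValueError("times must be positive")
    cap = min(censor_time, admin_cutoff)
    if latent_time <= cap:
        return latent_time, 1
    return cap, 0


def add_unmeasured_confounder(config: SimulationConfig, strength: float,
                              correlation: float,
                              anchor: str = "X2") -> SimulationConfig:
    """Return a config whose DGM includes a hidden confounder U.

    U affects both treatment allocation and the outcome hazard with the given
    ``strength`` (log-odds / log-hazard scale) and is correlated with the
    observed ``anchor`` covariate at ``correlation``. Downstream PS model
    specifications never see U.
    """
    from .config import UnmeasuredConfounder

    return config.with_confounder(
        UnmeasuredConfounder(strength=strength, correlation=correlation,
                             anchor=anchor))


def true_ps(config: SimulationConfig, cohort: Cohort) -> np.ndarray:
    """The data-generating propensity score e(x, S) evaluated exactly."""
    return expit(_treatment_logit(config, cohort.covariates, cohort.subset))


def true_marginal_effect(config: SimulationConfig, scenario: Scenario,
                         subset: int, N: int = 1_000_000,
                         estimand: Literal["ATT", "ATO"] = "ATT",
                         rng_state=None, swap_arms: bool = False) -> float:
    """Large-sample counterfactual marginal log hazard ratio in one subset.

    Simulates ``N`` individuals, keeps the target population (the naturally
    treated for ATT; the full subset weighted by e(x)(1-e(x)) at the true PS
    for ATO), draws both potential event times per individual (shared
    covariates, independent exponential draws per arm), administratively
    censors at ``admin_cutoff`` (random censoring is non-informative and is
    not applied), and fits a two-group proportional-hazards model on the
    stacked counterfactual data. ``swap_arms`` relabels the two
    counterfactual arms (a diagnostic: the returned log HR flips sign).
    """
    if subset not in (1, 2):
        raise ValueError("subset must be 1 or 2")
    streams = _resolve_streams(config.seed if rng_state is None else rng_state)
    X = _draw_covariates(config, N, streams["covariates"])
    S = np.where(streams["subset"].random(N) < config.p_s1, 1, 2)
    eta = _treatment_logit(config, X, S)
    e = expit(eta)
    Z = (streams["treatment"].random(N) < e).astype(int)

    keep = S == subset
    if estimand == "ATT":
        keep &= Z == 1
        weights = None
    elif estimand == "ATO":
        weights = (e * (1.0 - e))[keep]
    else:
        raise ValueError(f"unknown estimand {estimand!r}")
    m = int(keep.sum())
    if m == 0:
        raise RuntimeError(f"no individuals in the {estimand} target population "
                           f"of subset {subset}")

    lp0 = _outcome_log_hazard(config, X, S)[keep]
    theta = scenario.theta(subset)
    rng = streams["event"]
    t1 = rng.exponential(scale=np.exp(-(lp0 + theta)))
    t0 = rng.exponential(scale=np.exp(-lp0))
    if swap_arms:
        t1, t0 = t0, t1

    cutoff = config.admin_cutoff
    stacked = pd.DataFrame({
        "arm": np.concatenate([np.ones(m), np.zeros(m)]),
        "time": np.minimum(np.concatenate([t1, t0]), cutoff),
        "event": (np.concatenate([t1, t0]) <= cutoff).astype(int),
    })
    if weights is not None:
        stacked["w"] = np.concatenate([weights, weights])
    cph = CoxPHFitter()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(stacked, "time", "event", formula="arm",
                weights_col="w" if weights is not None else None)
    return float(cph.params_["arm"])
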