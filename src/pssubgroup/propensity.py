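"""Propensity-score model specifications and estimation.

Two strategies are compared throughout the package:

* **across** — one logistic model fit on the whole sample, with the subset
  indicator and (optionally) subset-by-covariate interaction terms in the
  linear predictor;
* **within** — a separate logistic model per subset, in which subset terms
  are meaningless (the subset is constant) and are silently dropped.

Five named model variants cover the designs of interest: the correctly
specified model (``true_ps``: all true confounders plus the S x X4 and
S x X9 interactions, the two covariates whose effect on treatment differs
between subsets), the same model plus a purely prognostic variable (X6) or
a pure instrument (X1), a model with interactions for every treatment
predictor, and a model with no interaction terms at all.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dgm import Cohort

Strategy = Literal["across", "within"]

#: covariates that affect both treatment allocation and the outcome hazard
TRUE_CONFOUNDERS: tuple[str, ...] = ("X2", "X4", "X5", "X7", "X8", "X9", "X10")

#: covariates whose treatment-allocation effect differs between subsets
SUBSET_MODIFIED: tuple[str, ...] = ("X4", "X9")

VARIANTS = ("true_ps", "with_prognostic", "with_instrumental",
            "all_interactions", "no_interactions")

_COEF_EXPLOSION = 15.0
_PROB_EPS = 1e-8


@dataclass(frozen=True)
class PSSpecification:
    """Term set of a propensity model.

    ``main_terms`` may include the subset indicator ``"S"`` (across strategy
    only); ``interaction_terms`` lists covariates interacted with the subset
    indicator.
    """

    variant: str
    main_terms: tuple[str, ...]
    interaction_terms: tuple[str, ...] = ()

    def terms_for_strategy(self, strategy: Strategy) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(main, interactions) actually entering the fit: within-subset fits
        drop the subset main effect and every S x X term."""
        if strategy == "within":
            return tuple(t for t in self.main_terms if t != "S"), ()
        return self.main_terms, self.interaction_terms


def build_ps_specification(variant: str,
                           custom_main: tuple[str, ...] | None = None,
                           custom_interactions: tuple[str, ...] = ()) -> PSSpecification:
    """Return the term set for a named PS model variant."""
    base_main = TRUE_CONFOUNDERS + ("S",)
    if variant == "true_ps":
        return PSSpecification(variant, base_main, SUBSET_MODIFIED)
    if variant == "with_prognostic":
        return PSSpecification(variant, base_main + ("X6",), SUBSET_MODIFIED)
    if variant == "with_instrumental":
        return PSSpecification(variant, base_main + ("X1",), SUBSET_MODIFIED)
    if variant == "all_interactions":
        return PSSpecification(
            variant, base_main, SUBSET_MODIFIED + ("X2", "X5", "X7", "X10"))
    if variant == "no_interactions":
        return PSSpecification(variant, base_main, ())
    if variant == "custom":
        if custom_main is None:
            raise ValueError("custom variant requires explicit main terms")
        return PSSpecification(variant, tuple(custom_main), tuple(custom_interactions))
    raise ValueError(f"unknown PS variant {variant!r}; known: {VARIANTS + ('custom',)}")


@dataclass
class PSResult:
    """Fitted propensity scores with provenance."""

    ps: np.ndarray
    strategy: Strategy
    spec: PSSpecification
    converged: dict[str, bool]
    fitted_subsets: tuple[int, ...]

    @property
    def logit_ps(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(self.ps / (1.0 - self.ps))

    @property
    def all_converged(self) -> bool:
        return all(self.converged.values())

    def converged_for(self, subset: int) -> bool:
        """Did the fit feeding this subset's PS converge?"""
        if self.strategy == "across":
            return self.converged["across"]
        return self.converged[f"subset{subset}"]

    def to_frame(self, cohort: Cohort) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(cohort.n),
            "S": cohort.subset,
            "Z": cohort.treatment,
            "ps": self.ps,
            "logit_ps": self.logit_ps,
            "strategy": self.strategy,
            "variant": self.spec.variant,
            "converged": np.repeat(self.all_converged, cohort.n),
        })


def _design_matrix(cohort: Cohort, main: tuple[str, ...],
                   interactions: tuple[str, ...],
                   rows: np.ndarray) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"const": np.ones(int(rows.sum()))}
    s_ind = (cohort.subset[rows] == 1).astype(float)
    for term in main:
        if term == "S":
            cols["S1"] = s_ind
        else:
            cols[term] = cohort.covariates[term].to_numpy()[rows]
    for cov in interactions:
        x = cohort.covariates[cov].to_numpy()[rows]
        cols[f"S1:{cov}"] = s_ind * x
    return pd.DataFrame(cols)


def _fit_logistic(y: np.ndarray, X: pd.DataFrame) -> tuple[np.ndarray | None, bool]:
    """MLE logistic fit; returns (fitted probabilities, converged flag).

    Non-convergence covers optimizer failure, rank deficiency, perfect or
    quasi separation (fitted probabilities at the boundary) and exploding
    coefficients.
    """
    if y.min() == y.max():
        return None, False
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        return None, False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception:
        return None, False
    fitted = np.asarray(res.predict(X))
    ok = bool(res.mle_retvals.get("converged", False))
    ok &= bool(np.all(np.abs(res.params) < _COEF_EXPLOSION))
    ok &= bool(np.all(fitted > _PROB_EPS) and np.all(fitted < 1 - _PROB_EPS))
    return fitted, ok


def estimate_ps(cohort: Cohort, spec: PSSpecification,
                strategy: Strategy) -> PSResult:
    """Estimate propensity scores under one strategy.

    A non-converged fit is flagged (never silently repaired): the harness
    counts the replication as a convergence failure for every method that
    consumes this PSResult.
    """
    if strategy not in ("across", "within"):
        raise ValueError(f"unknown strategy {strategy!r}")
    main, inter = spec.terms_for_strategy(strategy)
    ps = np.full(cohort.n, np.nan)
    converged: dict[str, bool] = {}

    if strategy == "across":
        rows = np.ones(cohort.n, dtype=bool)
        X = _design_matrix(cohort, main, inter, rows)
        fitted, ok = _fit_logistic(cohort.treatment.astype(float), X)
        if fitted is not None:
            ps[:] = fitted
        converged["across"] = ok
        fitted_subsets: tuple[int, ...] = (1, 2)
    else:
        for s in (1, 2):
            rows = cohort.subset == s
            if not rows.any():
                converged[f"subset{s}"] = False
                continue
            X = _design_matrix(cohort, main, inter, rows)
            fitted, ok = _fit_logistic(cohort.treatment[rows].astype(float), X)
            if fitted is not None:
                ps[rows] = fitted
            converged[f"subset{s}"] = ok
        fitted_subsets = (1, 2)

    return PSResult(ps=ps, strategy=strategy, spec=spec,
                    converged=converged, fitted_subsets=fitted_subsets)
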