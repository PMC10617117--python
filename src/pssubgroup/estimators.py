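"""PS-based estimators of the subset-specific marginal hazard ratio.

Four methods are provided, mirroring common observational-study practice:

* 1:1 greedy nearest-neighbour matching on the logit PS without replacement,
  caliper 0.2 (or 0.1) SD of the logit PS — robust sandwich variance
  clustered on matched pairs (ATT);
* the same matching with replacement in the control arm — control
  frequency weights with a sandwich variance clustered on subject identity,
  a frequency-weighted realisation of the replacement-aware variance (ATT);
* stabilized standardized-mortality-ratio weighting (SMRW): treated weight
  1, control weight ps/(1-ps) rescaled to mean one — bootstrap variance
  with the PS re-estimated in each resample (ATT);
* overlap weighting: treated weight 1-ps, control weight ps — robust
  sandwich variance with weights treated as fixed (ATO).

All point estimates come from a weighted Cox proportional-hazards model
with treatment as the sole covariate, fitted inside each subset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .dgm import Cohort
from .propensity import (PSResult, PSSpecification, Strategy,
                         build_ps_specification, estimate_ps)

Method = Literal["match_noreplace", "match_replace", "smrw", "overlap"]
VarianceMode = Literal["robust", "bootstrap", "replacement_aware"]

METHODS: tuple[str, ...] = ("match_noreplace", "match_replace", "smrw", "overlap")

#: estimand targeted by each method
ESTIMANDS: dict[str, str] = {
    "match_noreplace": "ATT", "match_replace": "ATT",
    "smrw": "ATT", "overlap": "ATO",
}


@dataclass
class MatchedSet:
    pairs: list[tuple[int, int]]
    with_replacement: bool
    caliper_width: float
    unmatched_treated: list[int]
    control_use_counts: dict[int, int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["treated_id", "control_id"])


@dataclass
class WeightVector:
    weights: np.ndarray
    scheme: Literal["SMRW", "overlap", "unit"]
    stabilized: bool = False
    valid: bool = True


@dataclass
class EffectEstimate:
    log_hr: float
    se: float
    ci_low: float
    ci_high: float
    estimand: str
    method: str
    subset: int
    n_effective: float
    converged: bool

    @staticmethod
    def failed(method: str, subset: int, estimand: str) -> "EffectEstimate":
        return EffectEstimate(np.nan, np.nan, np.nan, np.nan, estimand,
                              method, subset, 0.0, False)


def match(ps_result: PSResult, cohort: Cohort, caliper_sd: float = 0.2,
          with_replacement: bool = False, rng_state=None,
          pool: np.ndarray | None = None) -> MatchedSet:
    """Greedy 1:1 nearest-neighbour matching on the logit PS.

    Treated units are processed in a seeded random order; each is matched to
    the closest control within the caliper (``caliper_sd`` times the SD of
    the logit PS over the matching pool). Without replacement a used control
    is removed; ties break toward the lowest internal id. Treated units with
    no admissible control are recorded as unmatched, which is the source of
    the unmatched-patient bias this package studies.

    ``pool`` restricts matching to a boolean row mask (e.g. one subset).
    """
    rng = np.random.default_rng(rng_state)
    if pool is None:
        pool = np.ones(cohort.n, dtype=bool)
    lps = ps_result.logit_ps
    idx = np.flatnonzero(pool & np.isfinite(lps))
    treated = idx[cohort.treatment[idx] == 1]
    controls = idx[cohort.treatment[idx] == 0]
    if controls.size == 0:
        raise ValueError("matching pool contains no controls")
    if treated.size == 0:
        raise ValueError("matching pool contains no treated units")

    pool_sd = float(np.std(lps[idx], ddof=1))
    caliper = caliper_sd * pool_sd

    order = rng.permutation(treated.size)
    # controls sorted by logit PS, ties toward the lowest id
    c_order = np.lexsort((controls, lps[controls]))
    c_ids = controls[c_order]
    c_lps = lps[c_ids]

    pairs: list[tuple[int, int]] = []
    unmatched: list[int] = []
    use_counts: dict[int, int] = {}
    available = np.ones(c_ids.size, dtype=bool)
    n_avail = c_ids.size

    for t in treated[order]:
        target = lps[t]
        if with_replacement:
            j = _nearest_sorted(c_lps, c_ids, target)
        else:
            if n_avail == 0:
                unmatched.append(int(t))
                continue
            j = _nearest_available(c_lps, c_ids, available, target)
        if j is None or abs(c_lps[j] - target) > caliper:
            unmatched.append(int(t))
            continue
        c = int(c_ids[j])
        pairs.append((int(t), c))
        use_counts[c] = use_counts.get(c, 0) + 1
        if not with_replacement:
            available[j] = False
            n_avail -= 1

    return MatchedSet(pairs=pairs, with_replacement=with_replacement,
                      caliper_width=caliper, unmatched_treated=unmatched,
                      control_use_counts=use_counts)


def _min_id_at_values(c_lps: np.ndarray, c_ids: np.ndarray,
                      available: np.ndarray | None,
                      values: list[float]) -> int:
    """Among (available) controls whose logit PS equals one of ``values``
    exactly, the index with the lowest id. Only reached on distance ties,
    so the linear scans over duplicate runs stay cheap."""
    best = -1
    for v in set(values):
        lo = int(np.searchsorted(c_lps, v, side="left"))
        hi = int(np.searchsorted(c_lps, v, side="right"))
        for j in range(lo, hi):
            if available is not None and not available[j]:
                continue
            if best < 0 or c_ids[j] < c_ids[best]:
                best = j
    return best


def _nearest_sorted(c_lps: np.ndarray, c_ids: np.ndarray, target: float) -> int:
    """Index of the nearest control in a sorted array; ties to lowest id
    (including across duplicate-value runs)."""
    k = int(np.searchsorted(c_lps, target))
    cands = [j for j in (k - 1, k) if 0 <= j < c_lps.size]
    return _min_id_at_values(c_lps, c_ids, None,
                             _tied_values(c_lps, cands, target))


def _tied_values(c_lps: np.ndarray, cands: list[int],
                 target: float) -> list[float]:
    dists = [abs(c_lps[j] - target) for j in cands]
    dmin = min(dists)
    return [c_lps[j] for j, d in zip(cands, dists) if d == dmin]


def _nearest_available(c_lps: np.ndarray, c_ids: np.ndarray,
                       available: np.ndarray, target: float) -> int | None:
    k = int(np.searchsorted(c_lps, target))
    lo, hi = k - 1, k
    n = c_lps.size
    while lo >= 0 and not available[lo]:
        lo -= 1
    while hi < n and not available[hi]:
        hi += 1
    cands = [j for j in (lo, hi) if 0 <= j < n]
    if not cands:
        return None
    return _min_id_at_values(c_lps, c_ids, available,
                             _tied_values(c_lps, cands, target))


def smrw_weights(ps_result: PSResult, cohort: Cohort,
                 stabilize: bool = True) -> WeightVector:
    """Standardized mortality-ratio weights (ATT): treated 1, control odds.

    Stabilization rescales control weights to mean one within the control
    group — a constant factor that leaves the Cox point estimate invariant.
    A control PS of 1 gives an infinite weight and invalidates the vector.
    """
    ps = ps_result.ps
    z = cohort.treatment
    w = np.where(z == 1, 1.0, ps / (1.0 - ps))
    valid = bool(np.all(np.isfinite(w)))
    if stabilize and valid:
        ctrl = z == 0
        if ctrl.any():
            w[ctrl] = w[ctrl] / w[ctrl].mean()
    return WeightVector(weights=w, scheme="SMRW", stabilized=stabilize,
                        valid=valid)


def overlap_weights(ps_result: PSResult, cohort: Cohort) -> WeightVector:
    """Overlap weights (ATO): treated 1-ps, control ps."""
    ps = ps_result.ps
    w = np.where(cohort.treatment == 1, 1.0 - ps, ps)
    return WeightVector(weights=w, scheme="overlap",
                        valid=bool(np.all(np.isfinite(w))))


def _pseudo_population(cohort: Cohort, subset: int,
                       weights_or_matches) -> pd.DataFrame | None:
    """Assemble (id, Z, time, event, w, cluster) for one subset."""
    in_subset = cohort.subset == subset
    if isinstance(weights_or_matches, MatchedSet):
        ms = weights_or_matches
        rows: list[tuple[int, int, int]] = []  # (id, pair, count)
        for pair_id, (t, c) in enumerate(ms.pairs):
            if not in_subset[t]:
                continue
            rows.append((t, pair_id, 1))
            rows.append((c, pair_id, 1))
        if not rows:
            return None
        df = pd.DataFrame(rows, columns=["id", "pair", "count"])
        if ms.with_replacement:
            # frequency-weight controls by their use counts
            df = df.groupby("id", as_index=False).agg(
                count=("count", "sum"), pair=("pair", "min"))
            df["cluster"] = df["id"]
            df["w"] = df["count"].astype(float)
        else:
            df["cluster"] = df["pair"]
            df["w"] = 1.0
        ids = df["id"].to_numpy()
        out = pd.DataFrame({
            "id": ids,
            "Z": cohort.treatment[ids],
            "time": cohort.time[ids],
            "event": cohort.event[ids],
            "w": df["w"].to_numpy(),
            "cluster": df["cluster"].to_numpy(),
        })
        return out
    wv: WeightVector = weights_or_matches
    ids = np.flatnonzero(in_subset)
    w = wv.weights[ids] if wv.weights.shape[0] == cohort.n else wv.weights
    keep = w > 0
    ids, w = ids[keep], w[keep]
    if ids.size == 0:
        return None
    return pd.DataFrame({
        "id": ids, "Z": cohort.treatment[ids], "time": cohort.time[ids],
        "event": cohort.event[ids], "w": w, "cluster": ids,
    })


def _weighted_cox(df: pd.DataFrame, robust: bool = True,
                  cluster: bool = False) -> tuple[float, float] | None:
    """Fit time ~ Z with weights; returns (log HR, SE) or None."""
    events = df.loc[df["event"] == 1, "Z"]
    if events.empty or events.nunique() < 2:
        return None
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, "time", "event", formula="Z", weights_col="w",
                    robust=robust,
                    cluster_col="cluster" if cluster else None)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        return None
    log_hr = float(cph.params_["Z"])
    se = float(cph.standard_errors_["Z"])
    if not (np.isfinite(log_hr) and np.isfinite(se)):
        return None
    return log_hr, se


def fit_marginal_cox(cohort: Cohort, subset: int, weights_or_matches,
                     variance_mode: VarianceMode = "robust",
                     method: str | None = None,
                     ps_context: tuple[PSSpecification, Strategy] | None = None,
                     n_boot: int = 200, rng_state=None) -> EffectEstimate:
    """Marginal treatment effect (log HR) in one subset of a pseudo-population.

    ``weights_or_matches`` is a :class:`WeightVector` or :class:`MatchedSet`.
    Variance modes: ``robust`` (sandwich; clustered on pair id for matching
    without replacement), ``replacement_aware`` (frequency-weighted sandwich
    clustered on subject identity), ``bootstrap`` (resample the cohort,
    re-estimate the PS — requires ``ps_context=(spec, strategy)`` — and take
    the SD of the resampled estimates as the SE).
    """
    if method is None:
        if isinstance(weights_or_matches, MatchedSet):
            method = ("match_replace" if weights_or_matches.with_replacement
                      else "match_noreplace")
        else:
            method = "smrw" if weights_or_matches.scheme == "SMRW" else "overlap"
    estimand = ESTIMANDS.get(method, "ATT")

    if isinstance(weights_or_matches, WeightVector) and not weights_or_matches.valid:
        return EffectEstimate.failed(method, subset, estimand)
    df = _pseudo_population(cohort, subset, weights_or_matches)
    if df is None:
        return EffectEstimate.failed(method, subset, estimand)

    cluster = isinstance(weights_or_matches, MatchedSet)
    fit = _weighted_cox(df, robust=True, cluster=cluster)
    if fit is None:
        return EffectEstimate.failed(method, subset, estimand)
    log_hr, se = fit

    if variance_mode == "bootstrap":
        if ps_context is None:
            raise ValueError("bootstrap variance requires ps_context=(spec, strategy)")
        se_b = _bootstrap_se(cohort, subset, ps_context, method,
                             n_boot=n_boot, rng_state=rng_state)
        if se_b is None:
            return EffectEstimate.failed(method, subset, estimand)
        se = se_b

    zq = stats.norm.ppf(0.975)
    n_eff = float(df["w"].sum())
    return EffectEstimate(log_hr=log_hr, se=se, ci_low=log_hr - zq * se,
                          ci_high=log_hr + zq * se, estimand=estimand,
                          method=method, subset=subset, n_effective=n_eff,
                          converged=True)


def _bootstrap_se(cohort: Cohort, subset: int,
                  ps_context: tuple[PSSpecification, Strategy], method: str,
                  n_boot: int, rng_state=None) -> float | None:
    """Nonparametric bootstrap of the whole pipeline (PS re-estimated)."""
    spec, strategy = ps_context
    rng = np.random.default_rng(rng_state)
    frame = cohort.to_frame()
    estimates = []
    for _ in range(n_boot):
        take = rng.integers(0, cohort.n, cohort.n)
        boot = Cohort.from_frame(frame.iloc[take].reset_index(drop=True))
        ps_b = estimate_ps(boot, spec, strategy)
        if not ps_b.converged_for(subset):
            continue
        wv = (smrw_weights(ps_b, boot) if method == "smrw"
              else overlap_weights(ps_b, boot))
        if not wv.valid:
            continue
        df = _pseudo_population(boot, subset, wv)
        if df is None:
            continue
        fit = _weighted_cox(df, robust=False)
        if fit is not None:
            estimates.append(fit[0])
    if len(estimates) < max(10, n_boot // 4):
        return None
    return float(np.std(estimates, ddof=1))


def estimate_both_subsets(cohort: Cohort, strategy: Strategy, variant: str,
                          method: Method, caliper_sd: float = 0.2,
                          variance_mode: VarianceMode | None = None,
                          n_boot: int = 200, rng_state=None,
                          ps_result: PSResult | None = None,
                          ) -> tuple[EffectEstimate, EffectEstimate]:
    """Run the full pipeline and return one EffectEstimate per subset.

    Under the ``across`` strategy the PS is fit once on the whole cohort;
    matching and weighting are then carried out inside each subset stratum
    on that common PS. Under ``within`` everything happens inside the
    subset. Default variance modes follow the study design: sandwich for
    matching without replacement and overlap weighting, frequency-weighted
    sandwich for matching with replacement, bootstrap for SMRW.
    """
    if variance_mode is None:
        variance_mode = {"match_noreplace": "robust",
                         "match_replace": "replacement_aware",
                         "smrw": "bootstrap", "overlap": "robust"}[method]
    spec = build_ps_specification(variant)
    if ps_result is None:
        ps_result = estimate_ps(cohort, spec, strategy)
    ss = np.random.SeedSequence(rng_state) if not isinstance(
        rng_state, np.random.SeedSequence) else rng_state
    sub_seeds = ss.spawn(2)

    out: list[EffectEstimate] = []
    for subset, sseed in zip((1, 2), sub_seeds):
        estimand = ESTIMANDS[method]
        if not ps_result.converged_for(subset):
            out.append(EffectEstimate.failed(method, subset, estimand))
            continue
        try:
            if method in ("match_noreplace", "match_replace"):
                ms = match(ps_result, cohort, caliper_sd=caliper_sd,
                           with_replacement=(method == "match_replace"),
                           rng_state=sseed, pool=cohort.subset == subset)
                est = fit_marginal_cox(cohort, subset, ms,
                                       variance_mode=variance_mode, method=method)
            else:
                wv = (smrw_weights(ps_result, cohort) if method == "smrw"
                      else overlap_weights(ps_result, cohort))
                est = fit_marginal_cox(
                    cohort, subset, wv, variance_mode=variance_mode,
                    method=method, ps_context=(spec, ps_result.strategy),
                    n_boot=n_boot, rng_state=sseed)
        except ValueError:
            est = EffectEstimate.failed(method, subset, estimand)
        out.append(est)
    return out[0], out[1]
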