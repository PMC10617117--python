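"""Covariate-balance diagnostics: standardized mean differences, overlap
coefficients, and the long-format table behind a connect-S display.

SMD conventions: 0.1 and 0.2 are the usual thresholds of concern. The
overlap coefficient (OVL) integrates the pointwise minimum of the two
propensity-score densities: 1 means the treated and control PS
distributions coincide.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dgm import Cohort
from .estimators import MatchedSet, WeightVector

_OVL_BINS = 100  # fixed equal-width histogram on [0, 1]; no bandwidth choice


def smd_continuous(mean1: float, sd1: float, mean0: float, sd0: float) -> float:
    """|m1 - m0| / sqrt((s1^2 + s0^2)/2), the pooled-SD standardized
    difference for a continuous covariate."""
    if sd1 <= 0 or sd0 <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean1 - mean0) / math.sqrt((sd1 ** 2 + sd0 ** 2) / 2.0)


def smd_binary(p1: float, p0: float) -> float:
    """Standardized difference for a binary covariate from two prevalences."""
    if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0):
        raise ValueError("prevalences must lie strictly inside (0, 1)")
    return abs(p1 - p0) / math.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)


def _arm_rows(cohort: Cohort, weights_or_matches,
              subset: int | None) -> tuple[np.ndarray, np.ndarray]:
    """(row ids, weights) of the pseudo-population restricted to a subset."""
    mask = np.ones(cohort.n, dtype=bool) if subset is None else cohort.subset == subset
    if weights_or_matches is None:
        ids = np.flatnonzero(mask)
        return ids, np.ones(ids.size)
    if isinstance(weights_or_matches, MatchedSet):
        counts: dict[int, int] = {}
        for t, c in weights_or_matches.pairs:
            for i in (t, c):
                if mask[i]:
                    counts[i] = counts.get(i, 0) + 1
        ids = np.array(sorted(counts), dtype=int)
        w = np.array([counts[i] for i in ids], dtype=float)
        return ids, w
    wv: WeightVector = weights_or_matches
    ids = np.flatnonzero(mask)
    return ids, wv.weights[ids]


def weighted_smd(cohort: Cohort, weights_or_matches, covariate: str,
                 subset: int | None = None) -> float:
    """SMD of one covariate in a weighted or matched pseudo-population.

    Numerator: difference of weighted arm means. Denominator: the pooled
    *unweighted* original-sample arm SDs over the same subset, so that
    before/after values share one scale. ``weights_or_matches=None`` gives
    the raw (unadjusted) SMD.
    """
    ids, w = _arm_rows(cohort, weights_or_matches, subset)
    x = cohort.covariates[covariate].to_numpy()[ids]
    z = cohort.treatment[ids]
    w1, w0 = w[z == 1], w[z == 0]
    if w1.sum() <= 0 or w0.sum() <= 0:
        raise ValueError("empty pseudo-population in one arm")
    m1 = float(np.average(x[z == 1], weights=w1))
    m0 = float(np.average(x[z == 0], weights=w0))

    mask = np.ones(cohort.n, dtype=bool) if subset is None else cohort.subset == subset
    x_all = cohort.covariates[covariate].to_numpy()[mask]
    z_all = cohort.treatment[mask]
    s1 = float(np.std(x_all[z_all == 1], ddof=1))
    s0 = float(np.std(x_all[z_all == 0], ddof=1))
    denom = math.sqrt((s1 ** 2 + s0 ** 2) / 2.0)
    if denom <= 0:
        raise ValueError("degenerate covariate: zero variance in both arms")
    return abs(m1 - m0) / denom


def ovl(ps_treated: np.ndarray, ps_control: np.ndarray) -> float:
    """Overlap coefficient of two PS distributions.

    Estimated with a fixed 100-bin histogram on [0, 1]: the sum over bins of
    the minimum of the two bin proportions. Deterministic (no bandwidth);
    accurate to about +/-0.02 for moderate samples.
    """
    ps_treated = np.asarray(ps_treated, dtype=float)
    ps_control = np.asarray(ps_control, dtype=float)
    if ps_treated.size == 0 or ps_control.size == 0:
        raise ValueError("both arms must be non-empty")
    edges = np.linspace(0.0, 1.0, _OVL_BINS + 1)
    p1, _ = np.histogram(ps_treated, bins=edges)
    p0, _ = np.histogram(ps_control, bins=edges)
    return float(np.minimum(p1 / ps_treated.size, p0 / ps_control.size).sum())


def connect_s_table(
        balance_tables: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
) -> pd.DataFrame:
    """Assemble per-method balance tables into one long-format table.

    Input: a mapping method name -> DataFrame with columns (covariate,
    subset, smd) — as produced by :func:`balance_table` — or an iterable of
    such DataFrames carrying a ``method`` column. Output rows are
    (covariate, subset, method, smd, flag) where ``flag`` categorises the
    SMD at the conventional 0.1 / 0.2 thresholds, ready for a dot-matrix
    (connect-S) rendering.
    """
    frames = []
    if isinstance(balance_tables, Mapping):
        for name, tab in balance_tables.items():
            t = tab.copy()
            t["method"] = name
            frames.append(t)
    else:
        frames = [t.copy() for t in balance_tables]
    if not frames:
        return pd.DataFrame(columns=["covariate", "subset", "method", "smd", "flag"])
    out = pd.concat(frames, ignore_index=True)
    out["flag"] = pd.cut(out["smd"], bins=[-np.inf, 0.1, 0.2, np.inf],
                         labels=["<0.1", "0.1-0.2", ">0.2"])
    return out[["covariate", "subset", "method", "smd", "flag"]]


def balance_table(cohort: Cohort, weights_or_matches=None,
                  covariates: Iterable[str] | None = None,
                  subsets: Iterable[int | None] = (1, 2)) -> pd.DataFrame:
    """Per-covariate, per-subset SMDs for one method (None = unadjusted)."""
    covs = list(covariates) if covariates is not None else \
        [c for c in cohort.covariates.columns]
    rows = []
    for s in subsets:
        for cov in covs:
            rows.append({
                "covariate": cov,
                "subset": "all" if s is None else s,
                "smd": weighted_smd(cohort, weights_or_matches, cov, s),
            })
    return pd.DataFrame(rows)
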