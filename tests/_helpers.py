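"""Shared test utilities: hand-built cohorts and brute-force oracles."""
import numpy as np
import pandas as pd

from pssubgroup import build_ps_specification
from pssubgroup.dgm import Cohort
from pssubgroup.propensity import PSResult


def ps_cohort(logit_ps, Z, time=None, event=None):
    """A minimal cohort (all subset 1) with prescribed logit propensities."""
    n = len(Z)
    ps = 1 / (1 + np.exp(-np.asarray(logit_ps, dtype=float)))
    cov = pd.DataFrame({f"X{j}": np.zeros(n) for j in range(1, 11)})
    cohort = Cohort(covariates=cov, subset=np.ones(n, dtype=int),
                    treatment=np.asarray(Z, dtype=int),
                    time=np.asarray(time if time is not None else np.ones(n),
                                    dtype=float),
                    event=np.asarray(event if event is not None
                                     else np.ones(n), dtype=int))
    res = PSResult(ps=ps, strategy="across",
                   spec=build_ps_specification("true_ps"),
                   converged={"across": True}, fitted_subsets=(1, 2))
    return res, cohort


def greedy_match_oracle(lps, Z, caliper, order, with_replacement):
    """Exhaustive reference matcher: scan every control for each treated
    unit in the given processing order; nearest within caliper wins, ties to
    the lowest id; without replacement a used control leaves the pool."""
    treated = [i for i in range(len(Z)) if Z[i] == 1]
    controls = [i for i in range(len(Z)) if Z[i] == 0]
    used = set()
    pairs = []
    for t in (treated[k] for k in order):
        best, best_d = None, None
        for c in controls:
            if not with_replacement and c in used:
                continue
            d = abs(lps[t] - lps[c])
            if d > caliper:
                continue
            if best is None or d < best_d or (d == best_d and c < best):
                best, best_d = c, d
        if best is not None:
            pairs.append((t, best))
            used.add(best)
    return sorted(pairs)
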