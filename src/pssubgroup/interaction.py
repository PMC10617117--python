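"""Treatment-by-subset interaction tests on two subset-specific estimates.

The *quantitative* test asks whether the treatment effect differs in
magnitude between the subsets: with two subsets the heterogeneity statistic

    X^2 = (theta1 - theta2)^2 / (se1^2 + se2^2)

is referred to a chi-square with one degree of freedom (equivalently a Wald
z-test on the difference). The *qualitative* (crossing) test of Gail and
Simon asks whether effects point in opposite directions in different
subsets; its statistic min(Q-, Q+) follows a chi-bar-square mixture under
the null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import EffectEstimate


class NonConvergedError(ValueError):
    """An input estimate did not converge; the test cannot be performed."""


@dataclass(frozen=True)
class InteractionResult:
    statistic: float
    p_value: float
    test_type: str  # "quantitative" | "qualitative"
    significant_at_0_05: bool


def _check(est1: EffectEstimate, est2: EffectEstimate) -> None:
    for est in (est1, est2):
        if not est.converged or not np.isfinite(est.se) or est.se <= 0:
            raise NonConvergedError(
                "interaction test requires two converged estimates with se > 0")


def gail_simon_quantitative(est1: EffectEstimate,
                            est2: EffectEstimate) -> InteractionResult:
    """Two-subset quantitative (heterogeneity) interaction test."""
    _check(est1, est2)
    stat = (est1.log_hr - est2.log_hr) ** 2 / (est1.se ** 2 + est2.se ** 2)
    p = float(stats.chi2.sf(stat, df=1))
    return InteractionResult(float(stat), p, "quantitative", p < 0.05)


def gail_simon_qualitative(est1: EffectEstimate,
                           est2: EffectEstimate) -> InteractionResult:
    """Gail-Simon crossing (qualitative interaction) test, two subsets.

    Q- and Q+ accumulate the squared standardized effects on the negative
    and positive side; the statistic is min(Q-, Q+). With I=2 subsets the
    null distribution is the equal-weights mixture of a point mass at zero
    and chi-square(1): p = 0.5 * P(chi2_1 > statistic).
    """
    _check(est1, est2)
    thetas = np.array([est1.log_hr, est2.log_hr])
    ses = np.array([est1.se, est2.se])
    q_minus = float(np.sum((thetas < 0) * thetas ** 2 / ses ** 2))
    q_plus = float(np.sum((thetas > 0) * thetas ** 2 / ses ** 2))
    stat = min(q_minus, q_plus)
    p = float(0.5 * stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return InteractionResult(stat, p, "qualitative", p < 0.05)
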