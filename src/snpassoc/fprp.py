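"""False-positive report probability (FPRP) analysis.

FPRP is the posterior probability that a statistically significant
association is a false positive, given a prior probability pi that a
true association exists, the observed p-value alpha, and the power
1-beta of the study to detect a hypothesized true odds ratio OR1 at
significance level alpha:

    FPRP = alpha (1 - pi) / [ alpha (1 - pi) + (1 - beta) pi ]

The standard error of the log odds ratio is recovered from a reported
95% CI, power uses the two-sided normal approximation on the log-OR
scale, and findings are called noteworthy below a preset FPRP
threshold (0.2 here, evaluated over a descending grid of priors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .association import Z_95

DEFAULT_PRIORS = (0.25, 0.1, 0.01, 0.001, 0.0001)
DEFAULT_THRESHOLD = 0.2


@dataclass(frozen=True)
class FprpInput:
    label: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    detectable_or: Optional[float] = None  # OR1; policy default if None
    power: Optional[float] = None  # externally supplied 1-beta overrides

    def __post_init__(self):
        if not (0 < self.ci_low <= self.ci_high):
            raise ValueError(f"{self.label}: invalid CI ({self.ci_low}, {self.ci_high})")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"{self.label}: p-value must be in (0, 1]")


@dataclass(frozen=True)
class FprpResult:
    label: str
    se_log_or: float
    detectable_or: float
    power: float
    priors: tuple
    fprp_values: tuple
    noteworthy: tuple  # booleans, FPRP < threshold
    threshold: float


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """SE of the log odds ratio implied by a reported 95% CI."""
    if ci_low <= 0 or ci_high <= 0:
        raise ValueError("CI bounds must be positive")
    if ci_high < ci_low:
        raise ValueError("ci_high must be >= ci_low")
    return (np.log(ci_high) - np.log(ci_low)) / (2 * Z_95)


def detection_power(or1: float, se: float, alpha: float) -> float:
    """Power of the two-sided log-OR test of size ``alpha`` when the true
    odds ratio is ``or1`` and the estimator SE is ``se``.

    With mu = ln(OR1)/se and z_c the (1 - alpha/2) normal quantile:
    power = Phi(-z_c - mu) + 1 - Phi(z_c - mu).
    """
    if or1 <= 0:
        raise ValueError("detectable OR must be positive")
    if se <= 0:
        raise ValueError("SE must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    z_c = stats.norm.isf(alpha / 2)
    mu = np.log(or1) / se
    return float(stats.norm.cdf(-z_c - mu) + stats.norm.sf(z_c - mu))


def fprp(alpha: float, power: float, prior: float) -> float:
    """FPRP = alpha(1-pi) / (alpha(1-pi) + (1-beta) pi)."""
    if not (0 <= alpha <= 1 and 0 <= power <= 1 and 0 <= prior <= 1):
        raise ValueError("alpha, power and prior must lie in [0, 1]")
    num = alpha * (1 - prior)
    den = num + power * prior
    if den == 0:
        return 0.0 if prior > 0 else 1.0
    return num / den


def default_or1(or_estimate: float, protective: float = 0.67, risk: float = 1.5) -> float:
    """Default hypothesized true OR: 0.67 for protective estimates (<1),
    1.5 for risk estimates — reciprocal magnitudes by effect direction."""
    return protective if or_estimate < 1 else risk


def fprp_single(
    inp: FprpInput,
    priors: Sequence[float] = DEFAULT_PRIORS,
    threshold: float = DEFAULT_THRESHOLD,
    or1_policy=default_or1,
) -> FprpResult:
    se = se_from_ci(inp.ci_low, inp.ci_high)
    or1 = inp.detectable_or if inp.detectable_or is not None else or1_policy(inp.or_estimate)
    power = inp.power if inp.power is not None else detection_power(or1, se, inp.p_value)
    values = tuple(fprp(inp.p_value, power, pi) for pi in priors)
    return FprpResult(
        label=inp.label,
        se_log_or=float(se),
        detectable_or=float(or1),
        power=float(power),
        priors=tuple(priors),
        fprp_values=values,
        noteworthy=tuple(v < threshold for v in values),
        threshold=threshold,
    )


def fprp_table(
    inputs: Sequence[FprpInput],
    priors: Sequence[float] = DEFAULT_PRIORS,
    threshold: float = DEFAULT_THRESHOLD,
    or1_policy=default_or1,
) -> list:
    """FPRP grid for a list of findings (one result row per input)."""
    return [fprp_single(inp, priors, threshold, or1_policy) for inp in inputs]
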