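"""Power of the two-sample independent t-test used for cohort sizing.

The classifier score difference between cohorts is treated as a normal
shift of ``mean_diff`` (in score-percent units) with common standard
deviation ``sd``; the power of the two-sided pooled-variance t-test then
follows from the noncentral t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["PowerSpec", "t_test_power"]


@dataclass(frozen=True)
class PowerSpec:
    n_case: int
    n_control: int
    mean_diff: float
    sd: float
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def t_test_power(
    spec: PowerSpec | None = None,
    *,
    n_case: int | None = None,
    n_control: int | None = None,
    mean_diff: float | None = None,
    sd: float | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> float:
    """Power of the two-sided two-sample t-test.

    With the classical pooled-variance test (default), df = n1 + n2 - 2
    and the noncentrality parameter is mean_diff / (sd * sqrt(1/n1 + 1/n2));
    the power is P(|T'| > t_crit) under the noncentral t.  ``welch=True``
    uses the Welch-Satterthwaite df instead (identical here when both
    groups share ``sd``, up to the df formula).
    """
    if spec is None:
        spec = PowerSpec(n_case, n_control, mean_diff, sd, alpha)
    n1, n2 = spec.n_case, spec.n_control
    if welch:
        # equal variances assumed in the spec; Satterthwaite df under that assumption
        v1, v2 = spec.sd**2 / n1, spec.sd**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
    ncp = spec.mean_diff / (spec.sd * (1 / n1 + 1 / n2) ** 0.5)
    t_crit = stats.t.ppf(1 - spec.alpha / 2, df)
    nct = stats.nct(df, ncp)
    return float(1 - nct.cdf(t_crit) + nct.cdf(-t_crit))
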