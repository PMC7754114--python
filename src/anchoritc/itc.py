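"""Anchored indirect treatment comparison on the log hazard-ratio scale.

Two treatments A and B that were each compared directly against a shared
anchor regimen are compared indirectly as

    log HR(A vs B) = log HR(A vs anchor) − log HR(B vs anchor),
    SE² = SE_A² + SE_B²,

with a normal-approximation 95% interval (z = 1.96) and two-sided Wald p.
Absolute differences between the two data sources cancel through the anchor;
the SEs are treated as independent (the correlation induced when both direct
estimates share the same anchor arm is ignored, the standard approximation).

:func:`se_from_ci` backs the SE of a log HR out of a printed confidence
interval, which makes published hazard ratios directly usable as inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .survival import Z95, HREstimate

__all__ = [
    "ITCResult",
    "se_from_ci",
    "hr_estimate_from_ci",
    "bucher_combine",
    "percent_risk_reduction",
]


@dataclass(frozen=True)
class ITCResult:
    """An indirect comparison of two treatments through a common anchor."""

    comparison: tuple[str, str]
    anchor: str
    log_hr: float
    se: float
    inputs: tuple[HREstimate, HREstimate]

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def ci95(self) -> tuple[float, float]:
        return (math.exp(self.log_hr - Z95 * self.se), math.exp(self.log_hr + Z95 * self.se))

    @property
    def p(self) -> float:
        if self.se == 0:
            return 1.0 if self.log_hr == 0 else 0.0
        return float(2 * stats.norm.sf(abs(self.log_hr) / self.se))


def se_from_ci(hr: float, ci_lower: float, ci_upper: float) -> float:
    """SE of the log hazard ratio implied by a 95% CI:
    (ln upper − ln lower) / (2·1.96)."""
    if ci_lower <= 0 or ci_upper <= 0 or hr <= 0:
        raise ValueError("hazard ratio and CI bounds must be positive")
    if not (ci_lower <= hr <= ci_upper):
        raise ValueError("hazard ratio must lie within its CI")
    return (math.log(ci_upper) - math.log(ci_lower)) / (2 * Z95)


def hr_estimate_from_ci(
    hr: float,
    ci_lower: float,
    ci_upper: float,
    comparison: tuple[str, str] = ("treatment", "reference"),
    source: str = "",
    n: int = 0,
    events: int = 0,
    model: str = "reported",
) -> HREstimate:
    """Build an :class:`HREstimate` from a printed (HR, lower, upper) triple."""
    se = se_from_ci(hr, ci_lower, ci_upper)
    log_hr = math.log(hr)
    p = 1.0 if se == 0 else float(2 * stats.norm.sf(abs(log_hr) / se))
    return HREstimate(
        comparison=comparison,
        source=source,
        log_hr=log_hr,
        se_log_hr=se,
        n=n,
        events=events,
        model=model,
        p=p,
    )


def bucher_combine(a: HREstimate, b: HREstimate) -> ITCResult:
    """Anchored indirect comparison of ``a``'s treatment vs ``b``'s treatment.

    Both inputs must be direct comparisons against the same anchor label.
    """
    if a.anchor != b.anchor:
        raise ValueError(f"anchor mismatch: {a.anchor!r} vs {b.anchor!r}")
    return ITCResult(
        comparison=(a.comparison[0], b.comparison[0]),
        anchor=a.anchor,
        log_hr=a.log_hr - b.log_hr,
        se=math.hypot(a.se_log_hr, b.se_log_hr),
        inputs=(a, b),
    )


def percent_risk_reduction(result: ITCResult | float, rounded: bool = True) -> float:
    """100·(1 − HR); by convention reported rounded to a whole percent."""
    hr = result.hr if isinstance(result, ITCResult) else float(result)
    pct = 100.0 * (1.0 - hr)
    return float(round(pct)) if rounded else pct
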