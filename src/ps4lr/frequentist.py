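"""Observed-effect summaries: odds ratio, Woolf confidence interval,
Fisher's exact test, and the categorical 2015 ACMG/AMP PS4 verdict.

These frequentist quantities are reported alongside the likelihood ratio so
that the continuous evidence can be compared with what the 2015 framework
would have allocated.  The odds ratio is the plain cross-product estimate and
the interval is Woolf's log-OR method, exp(ln OR ± z·SE) with
SE = sqrt(1/a + 1/b + 1/c + 1/d).
"""

from __future__ import annotations

import math

from scipy.stats import fisher_exact, norm

from .models import (
    Acmg2015Verdict,
    CaseControlCounts,
    FrequentistSummary,
    NoCarriersError,
    Ps4lrError,
)

__all__ = [
    "observed_or",
    "woolf_ci",
    "woolf_se",
    "z_for_level",
    "fisher_exact_p",
    "acmg2015_ps4",
    "summarize",
]

# Fixed parameters of the 2015 ACMG/AMP PS4 rule.
_ACMG2015_OR_THRESHOLD = 5.0
_ACMG2015_ALPHA = 0.05
_ACMG2015_CI_LEVEL = 0.95


def z_for_level(level: float) -> float:
    """Two-sided normal quantile for a confidence level (e.g. 0.95 -> 1.960)."""
    if not 0 < level < 1:
        raise Ps4lrError(f"confidence level must lie in (0, 1), got {level!r}")
    return float(norm.ppf((1.0 + level) / 2.0))


def woolf_se(a: float, b: float, c: float, d: float) -> float:
    """Woolf standard error of the log odds ratio for cells a, b, c, d.

    Cells may be fractional (expected counts); all must be positive.
    """
    if min(a, b, c, d) <= 0:
        raise Ps4lrError("Woolf SE requires all four cells to be positive")
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def observed_or(counts: CaseControlCounts) -> float:
    """Cross-product odds ratio (a·d)/(b·c) of the observed 2x2 table.

    Returns ``inf`` when the variant is seen in cases but not in controls.
    Raises :class:`NoCarriersError` when there are no carriers at all.
    """
    k, m = counts.case_carriers, counts.control_carriers
    if k == 0 and m == 0:
        raise NoCarriersError("odds ratio undefined: no variant carriers in either series")
    if m == 0 or counts.case_non_carriers == 0:
        return math.inf
    return (k * counts.control_non_carriers) / (m * counts.case_non_carriers)


def woolf_ci(counts: CaseControlCounts, level: float = 0.95) -> tuple[float, float]:
    """Woolf confidence interval for the odds ratio.

    Returns ``(nan, nan)`` when any cell of the table is zero: the log-method
    interval is undefined there and no continuity correction is applied.
    """
    a, b = counts.case_carriers, counts.case_non_carriers
    c, d = counts.control_carriers, counts.control_non_carriers
    if min(a, b, c, d) < 1:
        return (math.nan, math.nan)
    z = z_for_level(level)
    log_or = math.log((a * d) / (b * c))
    half = z * woolf_se(a, b, c, d)
    return (math.exp(log_or - half), math.exp(log_or + half))


def fisher_exact_p(counts: CaseControlCounts) -> float:
    """Two-sided Fisher's exact p-value (point-probability method)."""
    return float(fisher_exact(counts.as_table(), alternative="two-sided").pvalue)


def acmg2015_ps4(counts: CaseControlCounts, rule: str = "ci") -> Acmg2015Verdict:
    """Categorical PS4 verdict under the 2015 ACMG/AMP framework.

    Parameters
    ----------
    rule : {"ci", "p"}
        ``"ci"`` (default): strong when observed OR >= 5 and the lower bound
        of the 95% CI exceeds 1.  ``"p"``: strong when observed OR >= 5 and
        the two-sided Fisher exact p < 0.05.  The two published phrasings of
        the rule are kept behind this switch rather than mixed.

    A table with an undefined CI (zero cell) returns ``NONE`` under the CI
    rule: the rule's lower-bound condition cannot be asserted.
    """
    if rule not in ("ci", "p"):
        raise Ps4lrError(f"unknown 2015-rule variant {rule!r} (expected 'ci' or 'p')")
    if counts.case_carriers == 0 and counts.control_carriers == 0:
        return Acmg2015Verdict.NONE
    orr = observed_or(counts)
    if orr < _ACMG2015_OR_THRESHOLD:
        return Acmg2015Verdict.NONE
    if rule == "ci":
        lower, _ = woolf_ci(counts, _ACMG2015_CI_LEVEL)
        ok = not math.isnan(lower) and lower > 1.0
    elif rule == "p":
        ok = fisher_exact_p(counts) < _ACMG2015_ALPHA
    else:
        raise Ps4lrError(f"unknown 2015-rule variant {rule!r} (expected 'ci' or 'p')")
    return Acmg2015Verdict.STRONG if ok else Acmg2015Verdict.NONE


def summarize(
    counts: CaseControlCounts, ci_level: float = 0.95, rule: str = "ci"
) -> FrequentistSummary:
    """All observed-effect columns for one table."""
    orr = observed_or(counts)
    lower, upper = woolf_ci(counts, ci_level)
    return FrequentistSummary(
        or_observed=orr,
        ci_lower=lower,
        ci_upper=upper,
        ci_level=ci_level,
        ci_defined=not math.isnan(lower),
        fisher_p=fisher_exact_p(counts),
        acmg2015_verdict=acmg2015_ps4(counts, rule=rule),
    )
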