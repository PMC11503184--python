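"""Integrated binomial likelihood-ratio core.

Given ``k`` variant carriers among the cases and ``m`` among the controls,
the ``n = k + m`` carriers are modelled as binomial draws with unknown
probability ``p`` of falling in the case series.  The steps are:

1. background odds of being a case among carriers, anchored on the observed
   odds among *non*-carriers;
2. conversion of each target OR into a probability threshold
   ``p = odds·OR / (1 + odds·OR)``;
3. integration of the binomial likelihood ``C(n,k) p^k (1-p)^(n-k)`` over
   the association region ``[p_assoc, 1]`` and the non-association region
   ``[0, p_nonassoc]`` via the regularized incomplete beta function with
   parameters ``(k+1, n-k+1)``;
4. the likelihood ratio towards pathogenicity is the ratio of the two areas,
   converted to exponent points by ``log`` base 2.08.

All areas and the LR are carried in natural-log space end to end: extreme but
legitimate inputs produce tail areas below double-precision range and LRs
around 1e19, so linear arithmetic alone is not safe.  The binomial
coefficient cancels algebraically in the ratio; it is included in the
reported region areas so that the total area identity ``1/(n+1)`` holds.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import mpmath
from scipy.special import betainc, betaln, expit

from . import diagnostics
from .frequentist import woolf_se, z_for_level
from .models import (
    CaseControlCounts,
    DegenerateTableError,
    LikelihoodRegions,
    LRResult,
    NoCarriersError,
    Ps4lrError,
    Strength,
    TargetORPair,
)

__all__ = [
    "EP_BASE",
    "background_case_odds",
    "probability_under_or",
    "likelihood_area",
    "log_likelihood_area",
    "compute_lr",
    "lr_to_ep",
    "ep_to_strength",
    "combine_eps",
]

#: Base of the exponent-point logarithm (2018 Bayesian points framework).
EP_BASE = 2.08
_LN_EP_BASE = math.log(EP_BASE)

# Below this, a regularized incomplete-beta difference from scipy is at risk
# of underflow or catastrophic cancellation and is recomputed with mpmath.
_FALLBACK_ABS = 1e-280
_FALLBACK_REL = 1e-4


def background_case_odds(counts: CaseControlCounts) -> float:
    """Expected background odds of being a case among variant carriers.

    Anchored on the equivalent observed odds among non-carriers:
    ``case_non_carriers / control_non_carriers``.
    """
    if counts.case_non_carriers < 1 or counts.control_non_carriers < 1:
        raise DegenerateTableError(
            "background odds undefined: a series has no non-carriers "
            "(every individual carries the variant)"
        )
    return counts.case_non_carriers / counts.control_non_carriers


def probability_under_or(background_odds: float, target_or: float) -> float:
    """Probability of a carrier being a case when the true OR equals a target.

    Scales the background odds by the target OR and converts to a
    probability: ``odds·OR / (1 + odds·OR)``.  Evaluated through the logistic
    function of the log odds, which stays accurate when the product
    over- or underflows.  Strictly increasing in both arguments.
    """
    for name, v in (("background_odds", background_odds), ("target_or", target_or)):
        if not (v > 0 and math.isfinite(v)):
            raise Ps4lrError(f"{name} must be positive and finite, got {v!r}")
    return float(expit(math.log(background_odds) + math.log(target_or)))


def _log_reg_inc_beta_diff(a: float, b: float, p_lo: float, p_hi: float) -> float:
    """log of I_{p_hi}(a, b) − I_{p_lo}(a, b), with a high-precision fallback.

    scipy's regularized incomplete beta is used when the difference is
    comfortably representable; otherwise the difference is recomputed with
    mpmath at 60 significant digits, which resolves tail masses far below
    double-precision range.
    """
    # Evaluate the difference on whichever side of the distribution keeps the
    # two terms small: CDFs directly when the interval sits in the lower half,
    # survival functions (the symmetry I_x(a,b) = 1 - I_{1-x}(b,a)) otherwise.
    # Subtracting two values near 1 loses all significant digits.
    cdf_hi = float(betainc(a, b, p_hi)) if p_hi < 1.0 else 1.0
    if cdf_hi <= 0.5:
        t_big = cdf_hi
        t_small = float(betainc(a, b, p_lo)) if p_lo > 0.0 else 0.0
    else:
        t_big = float(betainc(b, a, 1.0 - p_lo)) if p_lo > 0.0 else 1.0
        t_small = float(betainc(b, a, 1.0 - p_hi)) if p_hi < 1.0 else 0.0
    diff = t_big - t_small
    if diff > _FALLBACK_ABS and diff > _FALLBACK_REL * t_big:
        return math.log(diff)
    return _mp_log_reg_inc_beta_diff(a, b, p_lo, p_hi)


def _mp_log_reg_inc_beta_diff(a: float, b: float, p_lo: float, p_hi: float) -> float:
    """mpmath recomputation of the log incomplete-beta difference.

    Intervals anchored at an endpoint are rewritten as a single tail integral
    (exact, no cancellation).  Interior intervals are evaluated at escalating
    precision until at least ~20 significant digits survive the subtraction.
    """
    for dps in (60, 160, 400, 1000):
        with mpmath.mp.workdps(dps):
            if p_hi >= 1.0:
                v = mpmath.betainc(b, a, x1=0, x2=mpmath.mpf(1) - p_lo, regularized=True)
            elif p_lo <= 0.0:
                v = mpmath.betainc(a, b, x1=0, x2=p_hi, regularized=True)
            else:
                v = mpmath.betainc(a, b, x1=0, x2=p_hi, regularized=True) - mpmath.betainc(
                    a, b, x1=0, x2=p_lo, regularized=True
                )
            anchored = p_hi >= 1.0 or p_lo <= 0.0
            if v > 0 and (anchored or v > mpmath.mpf(10) ** -(dps - 20)):
                return float(mpmath.log(v))
            if v <= 0 and anchored:
                return -math.inf
    return float(mpmath.log(v)) if v > 0 else -math.inf


def log_likelihood_area(
    k: int,
    n: int,
    p_lo: float = 0.0,
    p_hi: float = 1.0,
    *,
    include_coefficient: bool = True,
) -> float:
    """Natural log of the integrated binomial likelihood over [p_lo, p_hi].

    The integrand is ``C(n,k) p^k (1-p)^(n-k)`` (or the same without the
    binomial coefficient).  Closed form: the regularized incomplete beta
    function with parameters ``(k+1, n-k+1)`` gives
    ``area = [I_{p_hi} - I_{p_lo}] / (n+1)`` with the coefficient included.
    """
    if n < 1:
        raise Ps4lrError("n must be >= 1")
    if not 0 <= k <= n:
        raise Ps4lrError(f"k must lie in [0, n], got k={k}, n={n}")
    if not (0.0 <= p_lo <= p_hi <= 1.0):
        raise Ps4lrError(f"bounds must satisfy 0 <= p_lo <= p_hi <= 1, got ({p_lo}, {p_hi})")
    a, b = k + 1, n - k + 1
    log_reg = _log_reg_inc_beta_diff(a, b, p_lo, p_hi)
    if include_coefficient:
        return log_reg - math.log(n + 1)
    return log_reg + float(betaln(a, b))


def likelihood_area(
    k: int,
    n: int,
    p_lo: float = 0.0,
    p_hi: float = 1.0,
    *,
    include_coefficient: bool = True,
) -> float:
    """Integrated binomial likelihood over [p_lo, p_hi] (linear scale).

    Underflows to 0.0 for extreme tails; use :func:`log_likelihood_area`
    when the magnitude matters there.
    """
    return math.exp(
        log_likelihood_area(k, n, p_lo, p_hi, include_coefficient=include_coefficient)
    )


def lr_to_ep(lr: float | None = None, *, log_lr: float | None = None) -> float:
    """Exponent points: log base 2.08 of the likelihood ratio.

    Accepts either the LR itself or its natural log (``log_lr``), the latter
    for values outside double range.
    """
    if (lr is None) == (log_lr is None):
        raise Ps4lrError("pass exactly one of lr or log_lr")
    if lr is not None:
        if not lr > 0:
            raise Ps4lrError(f"lr must be positive, got {lr!r}")
        log_lr = math.log(lr)
    return log_lr / _LN_EP_BASE


def ep_to_strength(ep: float) -> Strength:
    """Evidence band for an exponent-point value (boundaries ±1, ±2, ±4, ±8)."""
    if not math.isfinite(ep):
        raise Ps4lrError("ep must be finite")
    if ep >= 8:
        return Strength.VERY_STRONG_PATHOGENIC
    if ep >= 4:
        return Strength.STRONG_PATHOGENIC
    if ep >= 2:
        return Strength.MODERATE_PATHOGENIC
    if ep >= 1:
        return Strength.SUPPORTING_PATHOGENIC
    if ep > -1:
        return Strength.NEUTRAL
    if ep > -2:
        return Strength.SUPPORTING_BENIGN
    if ep > -4:
        return Strength.MODERATE_BENIGN
    if ep > -8:
        return Strength.STRONG_BENIGN
    return Strength.VERY_STRONG_BENIGN


def combine_eps(eps: Iterable[float]) -> float:
    """Sum exponent points from independently ascertained case-control series.

    Equals log base 2.08 of the product of the individual LRs.  Callers are
    responsible for independence of the underlying series.
    """
    return math.fsum(eps)


def _expected_woolf_se(counts: CaseControlCounts, p: float) -> float:
    """Woolf SE of the log OR on the *expected* table under a hypothesis.

    The carrier total ``n`` is held fixed and apportioned to the case column
    as ``n·p`` (fractional cells permitted); the non-carrier cells are the
    observed ones.
    """
    n = counts.carrier_total
    return woolf_se(
        n * p, n * (1.0 - p), counts.case_non_carriers, counts.control_non_carriers
    )


def _attenuated_targets(counts: CaseControlCounts, targets: TargetORPair) -> TargetORPair:
    """Effective target ORs after confidence-bound attenuation.

    The association target is replaced by the lower confidence bound of the
    OR estimate expected under the hypothesis of association
    (``or_assoc · exp(−z·SE)``); the non-association target by the upper
    bound under its hypothesis (``or_nonassoc · exp(+z·SE)``).  For weakly
    powered tables the two effective thresholds can cross; the overlapping
    regions are permitted (the resulting LR is aggressively attenuated) and
    downstream diagnostics flag the crossing.
    """
    odds = background_case_odds(counts)
    eff_assoc = targets.or_assoc
    eff_nonassoc = targets.or_nonassoc
    if targets.ci_level_assoc is not None:
        p = probability_under_or(odds, targets.or_assoc)
        se = _expected_woolf_se(counts, p)
        eff_assoc = targets.or_assoc * math.exp(-z_for_level(targets.ci_level_assoc) * se)
    if targets.ci_level_nonassoc is not None:
        p = probability_under_or(odds, targets.or_nonassoc)
        se = _expected_woolf_se(counts, p)
        eff_nonassoc = targets.or_nonassoc * math.exp(
            z_for_level(targets.ci_level_nonassoc) * se
        )
    return TargetORPair(
        or_assoc=eff_assoc,
        or_nonassoc=eff_nonassoc,
        allow_crossed=eff_assoc <= eff_nonassoc,
    )


def compute_lr(
    counts: CaseControlCounts,
    targets: TargetORPair | None = None,
    *,
    include_coefficient: bool = True,
    diagnostics_config: diagnostics.DiagnosticThresholds | None = None,
) -> LRResult:
    """Likelihood ratio towards pathogenicity for one 2x2 table.

    Parameters
    ----------
    counts
        The observed carrier counts; at least one carrier overall is
        required, and both series must contain at least one non-carrier.
    targets
        Hypothesis thresholds; defaults to OR >= 5 versus OR <= 1.  If
        confidence levels are set on the pair, the effective thresholds are
        attenuated before integration (see
        :func:`ps4lr.conservatism.attenuate_targets_by_ci`).
    include_coefficient
        Whether the binomial coefficient is carried in the two areas.  It
        cancels in the ratio, so the LR is identical either way; reported
        region areas always include it.
    """
    targets = targets if targets is not None else TargetORPair()
    n = counts.carrier_total
    if n < 1:
        raise NoCarriersError("no variant observations: carrier total is zero")
    effective = _attenuated_targets(counts, targets) if targets.wants_attenuation else targets

    odds = background_case_odds(counts)
    p_assoc = probability_under_or(odds, effective.or_assoc)
    p_nonassoc = probability_under_or(odds, effective.or_nonassoc)
    k = counts.case_carriers

    log_up = log_likelihood_area(k, n, p_assoc, 1.0, include_coefficient=include_coefficient)
    log_lo = log_likelihood_area(k, n, 0.0, p_nonassoc, include_coefficient=include_coefficient)
    log_lr = log_up - log_lo

    # Region areas are reported coefficient-included regardless of the LR path.
    log_area_assoc = log_likelihood_area(k, n, p_assoc, 1.0)
    log_area_nonassoc = log_likelihood_area(k, n, 0.0, p_nonassoc)
    regions = LikelihoodRegions(
        p_assoc=p_assoc,
        p_nonassoc=p_nonassoc,
        area_assoc=math.exp(log_area_assoc),
        area_nonassoc=math.exp(log_area_nonassoc),
        area_total=1.0 / (n + 1),
        log_area_assoc=log_area_assoc,
        log_area_nonassoc=log_area_nonassoc,
    )
    warnings = diagnostics.evaluate_warnings(
        counts, regions, diagnostics_config, crossed=effective.crossed
    )
    ep = lr_to_ep(log_lr=log_lr)
    return LRResult(
        lr=math.exp(log_lr) if log_lr < 709 else math.inf,
        log_lr=log_lr,
        ep=ep,
        strength=ep_to_strength(ep),
        warnings=warnings,
        regions=regions,
        counts=counts,
        targets=targets,
        effective_targets=effective,
    )
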