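"""Domain types for case-control likelihood-ratio evidence.

The central object is a 2x2 table of variant carriers and series totals in
cases and controls (:class:`CaseControlCounts`), evaluated against a pair of
pre-specified odds-ratio thresholds (:class:`TargetORPair`): the hypothesis of
association (true OR at or above the association target, e.g. OR >= 5) versus
the hypothesis of non-association (true OR at or below the non-association
target, typically OR <= 1).  Integrating the binomial likelihood of the
observed carrier split over each hypothesis region yields the likelihood ratio
towards pathogenicity, reported together with exponent points (log base 2.08)
and an ACMG/AMP-style strength band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Ps4lrError",
    "DegenerateTableError",
    "NoCarriersError",
    "CaseControlCounts",
    "TargetORPair",
    "LikelihoodRegions",
    "Strength",
    "LRResult",
    "FrequentistSummary",
    "Acmg2015Verdict",
    "CI_LEVELS",
]

#: Confidence levels accepted for target-OR attenuation.
CI_LEVELS = (0.70, 0.90, 0.95)


class Ps4lrError(ValueError):
    """Base class for input/contract violations."""


class DegenerateTableError(Ps4lrError):
    """A non-carrier cell is zero: every individual in a series carries the
    variant, so background case odds among non-carriers are undefined."""


class NoCarriersError(Ps4lrError):
    """No variant carriers in either series: there are no variant
    observations to model."""


@dataclass(frozen=True)
class CaseControlCounts:
    """Variant carrier counts and series totals for cases and controls.

    Attributes
    ----------
    case_carriers : int
        Carriers of the variant observed in the case series (``k``).
    case_total : int
        Total individuals in the case series.
    control_carriers : int
        Carriers observed in the control series (``m``).
    control_total : int
        Total individuals in the control series.

    Notes
    -----
    Throughout this package ``n`` denotes the *carrier* total
    ``case_carriers + control_carriers`` — the number of binomial trials in
    the likelihood model (each carrier is a draw that fell in either the case
    or the control series) — never the size of the case series.
    """

    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        for name in ("case_carriers", "case_total", "control_carriers", "control_total"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise Ps4lrError(f"{name} must be an integer, got {v!r}")
        if self.case_total <= 0 or self.control_total <= 0:
            raise Ps4lrError("series totals must be positive")
        if self.case_carriers < 0 or self.control_carriers < 0:
            raise Ps4lrError("carrier counts must be non-negative")
        if self.case_carriers > self.case_total:
            raise Ps4lrError(
                f"case_carriers ({self.case_carriers}) exceeds case_total ({self.case_total})"
            )
        if self.control_carriers > self.control_total:
            raise Ps4lrError(
                f"control_carriers ({self.control_carriers}) exceeds "
                f"control_total ({self.control_total})"
            )

    @property
    def carrier_total(self) -> int:
        """Total carriers across both series (binomial ``n``)."""
        return self.case_carriers + self.control_carriers

    @property
    def case_non_carriers(self) -> int:
        return self.case_total - self.case_carriers

    @property
    def control_non_carriers(self) -> int:
        return self.control_total - self.control_carriers

    def as_table(self) -> list[list[int]]:
        """The 2x2 table ``[[a, b], [c, d]]``: rows cases/controls, columns
        carriers/non-carriers."""
        return [
            [self.case_carriers, self.case_non_carriers],
            [self.control_carriers, self.control_non_carriers],
        ]


@dataclass(frozen=True)
class TargetORPair:
    """The pair of odds-ratio thresholds parameterising the two hypotheses.

    Attributes
    ----------
    or_assoc : float
        Target OR of association: the hypothesis of association is that the
        true OR is at or above this value.  Default 5, the disease-association
        threshold named by the 2015 ACMG/AMP framework.
    or_nonassoc : float
        Target OR of non-association (true OR at or below).  Default 1, which
        also encompasses protective effects.
    ci_level_assoc, ci_level_nonassoc : float or None
        Optional confidence level (0.70, 0.90 or 0.95) requesting attenuation
        of the corresponding target by a Woolf-type confidence bound derived
        from the expected counts under that hypothesis.
    allow_crossed : bool
        Internal escape used by the attenuation machinery: permits
        ``or_assoc <= or_nonassoc`` (overlapping hypothesis regions), which
        aggressive attenuation can produce.  Never set this directly.
    """

    or_assoc: float = 5.0
    or_nonassoc: float = 1.0
    ci_level_assoc: float | None = None
    ci_level_nonassoc: float | None = None
    allow_crossed: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.or_assoc > 0 and math.isfinite(self.or_assoc)):
            raise Ps4lrError("or_assoc must be positive and finite")
        if not (self.or_nonassoc > 0 and math.isfinite(self.or_nonassoc)):
            raise Ps4lrError("or_nonassoc must be positive and finite")
        if not self.allow_crossed and not self.or_assoc > self.or_nonassoc:
            raise Ps4lrError(
                f"or_assoc ({self.or_assoc}) must strictly exceed "
                f"or_nonassoc ({self.or_nonassoc})"
            )
        for name in ("ci_level_assoc", "ci_level_nonassoc"):
            level = getattr(self, name)
            if level is not None and level not in CI_LEVELS:
                raise Ps4lrError(f"{name} must be one of {CI_LEVELS}, got {level!r}")

    @property
    def wants_attenuation(self) -> bool:
        return self.ci_level_assoc is not None or self.ci_level_nonassoc is not None

    @property
    def crossed(self) -> bool:
        """True when the (effective) thresholds are inverted/overlapping."""
        return self.or_assoc <= self.or_nonassoc


@dataclass(frozen=True)
class LikelihoodRegions:
    """Integrated binomial likelihood over the two hypothesis regions.

    Areas are coefficient-included integrals of ``C(n,k) p^k (1-p)^(n-k)``,
    so the total over [0, 1] is exactly ``1/(n+1)``.  ``log_area_*`` carry the
    natural-log values and remain finite when the linear areas underflow.
    """

    p_assoc: float
    p_nonassoc: float
    area_assoc: float
    area_nonassoc: float
    area_total: float
    log_area_assoc: float
    log_area_nonassoc: float

    @property
    def occupancy(self) -> float:
        """Fraction of the total likelihood space occupied by the two
        hypothesis regions.  May exceed 1 only when attenuation produced
        overlapping regions (crossed thresholds)."""
        return (self.area_assoc + self.area_nonassoc) / self.area_total


class Strength(str, Enum):
    """Evidence bands of the 2018 Bayesian points framework, at exponent-point
    boundaries +/-1, +/-2, +/-4, +/-8 (LR 2.08, 4.33, 18.72, 350.4 and
    reciprocals)."""

    VERY_STRONG_PATHOGENIC = "very_strong_pathogenic"
    STRONG_PATHOGENIC = "strong_pathogenic"
    MODERATE_PATHOGENIC = "moderate_pathogenic"
    SUPPORTING_PATHOGENIC = "supporting_pathogenic"
    NEUTRAL = "neutral"
    SUPPORTING_BENIGN = "supporting_benign"
    MODERATE_BENIGN = "moderate_benign"
    STRONG_BENIGN = "strong_benign"
    VERY_STRONG_BENIGN = "very_strong_benign"


@dataclass(frozen=True)
class LRResult:
    """Outcome of a likelihood-ratio evaluation.

    ``lr`` is ``exp(log_lr)`` and may overflow to ``inf`` for extreme
    evidence; ``log_lr`` and ``ep`` are always finite and are the values to
    combine across independent series.
    """

    lr: float
    log_lr: float
    ep: float
    strength: Strength
    warnings: "object"  # diagnostics.WarningFlags; typed loosely to avoid a cycle
    regions: LikelihoodRegions
    counts: CaseControlCounts
    targets: TargetORPair
    effective_targets: TargetORPair

    @property
    def warning_names(self) -> frozenset[str]:
        return self.warnings.active


class Acmg2015Verdict(str, Enum):
    """Categorical PS4 outcome under the original 2015 framework rule."""

    STRONG = "strong"
    NONE = "none"


@dataclass(frozen=True)
class FrequentistSummary:
    """Observed-effect summary for side-by-side reporting with the LR.

    ``or_observed`` is the cross-product odds ratio (``inf`` when the variant
    is absent from controls but present in cases); the confidence interval is
    Woolf's log-OR interval and is undefined (NaN bounds, ``ci_defined``
    False) when any cell of the 2x2 table is zero — no continuity correction
    is applied silently.
    """

    or_observed: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    ci_defined: bool
    fisher_p: float
    acmg2015_verdict: Acmg2015Verdict
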