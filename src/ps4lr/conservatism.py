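"""Options for introducing caution ("conservatism") into the evidence.

When there is uncertainty about genotyping, phenotyping, ancestry matching or
the case-series denominator, the output LR can be deliberately dampened.
Four mechanisms are provided:

1. raise the target OR of non-association (a stricter opposing hypothesis);
2. replace each target OR by a confidence bound derived from the expected
   counts under its hypothesis (punitive for small or unbalanced tables);
3. sensitivity analysis — recompute after removing case observations and/or
   adding control observations;
4. disallow pathogenic-direction application when there is a single case
   observation (the limit of the sensitivity principle: one case sensitivity-
   tested is zero cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from . import core
from .models import CaseControlCounts, LRResult, Ps4lrError, TargetORPair

__all__ = [
    "AttenuationMode",
    "AttenuationSpec",
    "adjust_opposing_hypothesis",
    "attenuate_targets_by_ci",
    "sensitivity_analysis",
    "enforce_single_case_rule",
    "apply_attenuation",
]


class AttenuationMode(str, Enum):
    NONE = "none"
    OPPOSING_HYPOTHESIS = "opposing_hypothesis"
    CI_ON_TARGETS = "ci_on_targets"
    SENSITIVITY = "sensitivity"


@dataclass(frozen=True)
class AttenuationSpec:
    """Selected conservatism mode plus the fields that mode requires."""

    mode: AttenuationMode = AttenuationMode.NONE
    raised_nonassoc_or: float | None = None
    ci_level: float | None = None
    case_decrement: int | None = None
    control_increment: int | None = None

    def __post_init__(self) -> None:
        relevant = {
            AttenuationMode.NONE: set(),
            AttenuationMode.OPPOSING_HYPOTHESIS: {"raised_nonassoc_or"},
            AttenuationMode.CI_ON_TARGETS: {"ci_level"},
            AttenuationMode.SENSITIVITY: {"case_decrement", "control_increment"},
        }[AttenuationMode(self.mode)]
        for name in ("raised_nonassoc_or", "ci_level", "case_decrement", "control_increment"):
            set_ = getattr(self, name) is not None
            if set_ and name not in relevant:
                raise Ps4lrError(f"{name} is not applicable to mode {self.mode!r}")
            if not set_ and name in relevant:
                raise Ps4lrError(f"mode {self.mode!r} requires {name}")


def adjust_opposing_hypothesis(
    targets: TargetORPair, raised_nonassoc_or: float
) -> TargetORPair:
    """Raise the target OR of non-association.

    Enlarging the non-association region can only increase the denominator of
    the LR, so the downstream LR is non-increasing in the raised value.
    """
    if not raised_nonassoc_or > 0:
        raise Ps4lrError("raised_nonassoc_or must be positive")
    if raised_nonassoc_or >= targets.or_assoc:
        raise Ps4lrError(
            f"raised non-association OR ({raised_nonassoc_or}) must stay below "
            f"the association OR ({targets.or_assoc}): the hypotheses would overlap"
        )
    if raised_nonassoc_or == targets.or_nonassoc:
        return targets
    return TargetORPair(
        or_assoc=targets.or_assoc,
        or_nonassoc=raised_nonassoc_or,
        ci_level_assoc=targets.ci_level_assoc,
        ci_level_nonassoc=targets.ci_level_nonassoc,
    )


def attenuate_targets_by_ci(
    counts: CaseControlCounts, targets: TargetORPair
) -> TargetORPair:
    """Replace each target OR by a confidence bound under its own hypothesis.

    For the association side, an expected 2x2 table is built by apportioning
    the observed carrier total across cases and controls according to the
    case probability implied by ``or_assoc`` (fractional cells permitted;
    non-carrier cells are the observed ones); the effective threshold is
    ``or_assoc · exp(−z·SE)`` with the Woolf SE of that table.  Symmetrically
    the non-association target becomes ``or_nonassoc · exp(+z·SE)`` under its
    expected table.  The resulting LR is attenuated toward 1 relative to the
    unadjusted LR.

    For low carrier counts or very unbalanced series the standard errors are
    large and the two effective thresholds may cross; the overlapping
    hypothesis regions are still integrable and the crossing is surfaced as
    the ``ci_thresholds_crossed`` warning on the result.  Targets with no
    confidence level set are returned unchanged.
    """
    if not targets.wants_attenuation:
        return targets
    if counts.carrier_total < 1:
        raise Ps4lrError("attenuation requires at least one variant carrier")
    return core._attenuated_targets(counts, targets)


def sensitivity_analysis(
    counts: CaseControlCounts,
    targets: TargetORPair,
    case_decrement: int = 0,
    control_increment: int = 0,
) -> tuple[LRResult, LRResult]:
    """Recompute the LR after perturbing the table against the evidence.

    Removes ``case_decrement`` case carriers and/or adds
    ``control_increment`` control carriers (series totals unchanged), and
    returns ``(original, perturbed)`` results.  The perturbed LR never
    exceeds the original.
    """
    if case_decrement < 0 or control_increment < 0:
        raise Ps4lrError("perturbations must be non-negative")
    if case_decrement > counts.case_carriers:
        raise Ps4lrError(
            f"case_decrement ({case_decrement}) exceeds case carriers "
            f"({counts.case_carriers})"
        )
    perturbed_counts = CaseControlCounts(
        case_carriers=counts.case_carriers - case_decrement,
        case_total=counts.case_total,
        control_carriers=counts.control_carriers + control_increment,
        control_total=counts.control_total,
    )
    original = core.compute_lr(counts, targets)
    perturbed = core.compute_lr(perturbed_counts, targets)
    return original, perturbed


def enforce_single_case_rule(counts: CaseControlCounts) -> bool:
    """Whether pathogenic-direction application is permitted for this table.

    Returns False exactly when there is a single variant observation in
    cases: one case sensitivity-tested down is zero cases, so evidence
    towards pathogenicity resting on a single case observation is disallowed.
    Zero case carriers are permitted (benign-direction use; the zero-case
    diagnostics still apply).  Callers choose hard refusal versus
    warn-and-proceed; the command-line interface refuses by default.
    """
    return counts.case_carriers != 1


def apply_attenuation(
    counts: CaseControlCounts, targets: TargetORPair, spec: AttenuationSpec
) -> TargetORPair:
    """Resolve an :class:`AttenuationSpec` into effective targets.

    Sensitivity mode perturbs counts, not targets, and is handled by
    :func:`sensitivity_analysis`; here it returns the targets unchanged.
    """
    mode = AttenuationMode(spec.mode)
    if mode is AttenuationMode.OPPOSING_HYPOTHESIS:
        return adjust_opposing_hypothesis(targets, spec.raised_nonassoc_or)
    if mode is AttenuationMode.CI_ON_TARGETS:
        return attenuate_targets_by_ci(
            counts,
            TargetORPair(
                or_assoc=targets.or_assoc,
                or_nonassoc=targets.or_nonassoc,
                ci_level_assoc=spec.ci_level,
                ci_level_nonassoc=spec.ci_level,
            ),
        )
    return targets
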