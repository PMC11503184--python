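"""Edge-case warning flags.

Two data configurations are known to produce likelihood ratios that demand
caution even though the arithmetic is sound:

1. *Low likelihood-space occupancy* — a well-powered signal for a variant of
   intermediate effect places both hypothesis regions far out in the tails of
   the likelihood curve.  The ratio of two minuscule areas can be large, yet
   the true OR almost certainly lies between the two targets.
2. *Zero case observations against a dramatically larger control series* —
   the case-frequency estimate is so imprecise that the resulting LR is
   unstable.

A third flag marks a single variant observation in cases, where phenotype or
genotype error in one individual would dominate the result.  Flags never
alter the computed LR; they annotate it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import CaseControlCounts, LikelihoodRegions

__all__ = ["DiagnosticThresholds", "WarningFlags", "occupancy", "evaluate_warnings"]


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Configurable cutoffs for the warning flags.

    Neither cutoff has a canonical published value; the defaults below are
    this package's own choices and can be overridden everywhere they are
    consumed.

    Attributes
    ----------
    low_occupancy_cutoff : float
        Flag when the two hypothesis regions jointly capture less than this
        fraction of the total area under the likelihood curve.  Default 0.05.
    imbalance_ratio : float
        Minimum control:case series-size ratio for the zero-case-observation
        warning.  Default 100.
    """

    low_occupancy_cutoff: float = 0.05
    imbalance_ratio: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.low_occupancy_cutoff <= 1:
            raise ValueError("low_occupancy_cutoff must lie in (0, 1]")
        if self.imbalance_ratio < 1:
            raise ValueError("imbalance_ratio must be >= 1")


@dataclass(frozen=True)
class WarningFlags:
    """Warning annotations attached to an LR result."""

    low_occupancy: bool
    zero_case_unbalanced: bool
    single_case_observation: bool
    ci_thresholds_crossed: bool
    occupancy_value: float
    thresholds_used: DiagnosticThresholds

    @property
    def active(self) -> frozenset[str]:
        """Names of the flags that are set."""
        return frozenset(
            name
            for name in (
                "low_occupancy",
                "zero_case_unbalanced",
                "single_case_observation",
                "ci_thresholds_crossed",
            )
            if getattr(self, name)
        )


def occupancy(regions: LikelihoodRegions) -> float:
    """Fraction of total likelihood space captured by the hypothesis regions.

    ``(area_assoc + area_nonassoc) / area_total``.  Equals 1 when the two
    regions partition the whole interval, and approaches 0 for a well-powered
    intermediate-effect signal.
    """
    return regions.occupancy


def evaluate_warnings(
    counts: CaseControlCounts,
    regions: LikelihoodRegions,
    config: DiagnosticThresholds | None = None,
    *,
    crossed: bool = False,
) -> WarningFlags:
    """Evaluate all warning flags for one result.

    Flags are pure functions of the inputs and configuration:

    - ``low_occupancy``: occupancy below ``config.low_occupancy_cutoff``;
    - ``zero_case_unbalanced``: no case carriers, at least one control
      carrier, and a control series at least ``config.imbalance_ratio`` times
      the case series;
    - ``single_case_observation``: exactly one case carrier;
    - ``ci_thresholds_crossed``: target-OR attenuation inverted the
      effective thresholds (overlapping hypothesis regions).
    """
    config = config or DiagnosticThresholds()
    occ = regions.occupancy
    return WarningFlags(
        low_occupancy=occ < config.low_occupancy_cutoff,
        zero_case_unbalanced=(
            counts.case_carriers == 0
            and counts.control_carriers >= 1
            and counts.control_total / counts.case_total >= config.imbalance_ratio
        ),
        single_case_observation=counts.case_carriers == 1,
        ci_thresholds_crossed=crossed,
        occupancy_value=occ,
        thresholds_used=config,
    )
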