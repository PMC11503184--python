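"""Batch evaluation and file I/O.

Input is a tab-separated table with a header row.  Required columns:
``label``, ``case_carriers``, ``case_total``, ``control_carriers``,
``control_total``; optional columns ``or_assoc``, ``or_nonassoc``,
``ci_level_assoc``, ``ci_level_nonassoc`` (``.`` or empty marks a missing
optional, which takes the default of 5, 1, none, none).  Output is one row
per scenario carrying the observed-effect columns, the LR/EP with strength
band and warning flags, in full precision plus display-rounded columns, or a
JSON document with the same content nested per record.

Row-level problems (malformed integers, carriers exceeding totals) are
reported per row and do not abort the batch; only a malformed header does.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np
from scipy.special import gammaln

from . import conservatism, core, frequentist
from .diagnostics import DiagnosticThresholds
from .models import (
    CaseControlCounts,
    FrequentistSummary,
    LRResult,
    Ps4lrError,
    TargetORPair,
)

__all__ = [
    "ScenarioRecord",
    "RowError",
    "BatchParseResult",
    "BatchHeaderError",
    "BatchResultRow",
    "parse_batch",
    "run_batch",
    "export_curve",
    "CurveExport",
    "format_lr",
    "format_ep",
    "results_to_tsv",
    "results_to_json",
    "write_curve_tsv",
]

REQUIRED_COLUMNS = (
    "label",
    "case_carriers",
    "case_total",
    "control_carriers",
    "control_total",
)
OPTIONAL_COLUMNS = ("or_assoc", "or_nonassoc", "ci_level_assoc", "ci_level_nonassoc")
MISSING = "."


class BatchHeaderError(Ps4lrError):
    """The header row is missing or lacks required columns (aborts the batch)."""


@dataclass(frozen=True)
class ScenarioRecord:
    """One labelled scenario of a batch."""

    label: str
    counts: CaseControlCounts
    targets: TargetORPair = field(default_factory=TargetORPair)


@dataclass(frozen=True)
class RowError:
    """A per-row parse failure (1-based data row number)."""

    row_number: int
    message: str


@dataclass(frozen=True)
class BatchParseResult:
    records: list[ScenarioRecord]
    errors: list[RowError]


def _parse_int(raw: str, name: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise Ps4lrError(f"{name}: {raw!r} is not an integer") from None


def _parse_optional_float(raw: str | None, name: str) -> float | None:
    if raw is None or raw.strip() in ("", MISSING):
        return None
    try:
        return float(raw)
    except ValueError:
        raise Ps4lrError(f"{name}: {raw!r} is not a number") from None


def parse_batch(stream: IO[str] | Iterable[str]) -> BatchParseResult:
    """Parse a batch TSV into scenario records.

    Returns records for every valid row and a :class:`RowError` for every
    invalid one.  Duplicate labels and missing required columns in the header
    raise :class:`BatchHeaderError`.
    """
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None:
        return BatchParseResult([], [])
    missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise BatchHeaderError(f"header is missing required column(s): {', '.join(missing)}")

    records: list[ScenarioRecord] = []
    errors: list[RowError] = []
    seen: set[str] = set()
    for row_number, row in enumerate(reader, start=1):
        try:
            label = (row.get("label") or "").strip()
            if not label:
                raise Ps4lrError("empty label")
            if label in seen:
                raise Ps4lrError(f"duplicate label {label!r}")
            counts = CaseControlCounts(
                case_carriers=_parse_int(row["case_carriers"], "case_carriers"),
                case_total=_parse_int(row["case_total"], "case_total"),
                control_carriers=_parse_int(row["control_carriers"], "control_carriers"),
                control_total=_parse_int(row["control_total"], "control_total"),
            )
            targets = TargetORPair(
                or_assoc=_parse_optional_float(row.get("or_assoc"), "or_assoc") or 5.0,
                or_nonassoc=_parse_optional_float(row.get("or_nonassoc"), "or_nonassoc")
                or 1.0,
                ci_level_assoc=_parse_optional_float(
                    row.get("ci_level_assoc"), "ci_level_assoc"
                ),
                ci_level_nonassoc=_parse_optional_float(
                    row.get("ci_level_nonassoc"), "ci_level_nonassoc"
                ),
            )
            seen.add(label)
            records.append(ScenarioRecord(label=label, counts=counts, targets=targets))
        except (Ps4lrError, KeyError) as exc:
            errors.append(RowError(row_number, f"row {row_number}: {exc}"))
    return BatchParseResult(records, errors)


@dataclass(frozen=True)
class BatchResultRow:
    """Evaluated outcome for one record; exactly one of result/error is set."""

    label: str
    record: ScenarioRecord | None
    result: LRResult | None
    summary: FrequentistSummary | None
    error: str | None = None


def run_batch(
    records: Iterable[ScenarioRecord],
    *,
    allow_single_case: bool = False,
    diagnostics_config: DiagnosticThresholds | None = None,
    acmg_rule: str = "ci",
) -> list[BatchResultRow]:
    """Evaluate records deterministically; failures are isolated per record.

    By default a record with a single case observation whose evidence points
    towards pathogenicity is refused (see
    :func:`ps4lr.conservatism.enforce_single_case_rule`); benign-direction
    single-case results are returned with their warning flag set.
    """
    rows: list[BatchResultRow] = []
    for record in records:
        try:
            result = core.compute_lr(
                record.counts, record.targets, diagnostics_config=diagnostics_config
            )
            if (
                not allow_single_case
                and not conservatism.enforce_single_case_rule(record.counts)
                and result.ep > 0
            ):
                raise Ps4lrError(
                    "pathogenic-direction evidence from a single case observation "
                    "is disallowed (pass allow_single_case to override)"
                )
            summary = frequentist.summarize(record.counts, rule=acmg_rule)
            rows.append(BatchResultRow(record.label, record, result, summary))
        except Ps4lrError as exc:
            rows.append(BatchResultRow(record.label, record, None, None, error=str(exc)))
    return rows


# ---------------------------------------------------------------------------
# Display formatting (mirrors the conventions of the reference scenarios:
# LR with 2 decimals below 100, otherwise 3-significant-figure scientific
# notation; EP to 1 decimal).  Internal values are never rounded.


def format_lr(lr: float, *, log_lr: float | None = None) -> str:
    """Display form of an LR.  ``log_lr`` takes over when ``lr`` overflows."""
    if not math.isfinite(lr):
        if log_lr is None or not math.isfinite(log_lr):
            return "inf"
        exp10 = log_lr / math.log(10.0)
        mantissa = 10 ** (exp10 - math.floor(exp10))
        return f"{mantissa:.2f}e{int(math.floor(exp10)):+d}"
    if 0.01 <= lr < 100:
        return f"{lr:.2f}"
    return f"{lr:.2e}"


def format_ep(ep: float) -> str:
    return f"{ep:.1f}"


_FULL = "%.17g"


def _row_dict(row: BatchResultRow) -> dict:
    """Nested full-precision record for JSON output."""
    d: dict = {"label": row.label}
    if row.record is not None:
        c, t = row.record.counts, row.record.targets
        d["inputs"] = {
            "case_carriers": c.case_carriers,
            "case_total": c.case_total,
            "control_carriers": c.control_carriers,
            "control_total": c.control_total,
            "or_assoc": t.or_assoc,
            "or_nonassoc": t.or_nonassoc,
            "ci_level_assoc": t.ci_level_assoc,
            "ci_level_nonassoc": t.ci_level_nonassoc,
        }
    if row.error is not None:
        d["error"] = row.error
        return d
    r, s = row.result, row.summary
    d["effective_targets"] = {
        "or_assoc": r.effective_targets.or_assoc,
        "or_nonassoc": r.effective_targets.or_nonassoc,
    }
    d["frequentist"] = {
        "or_observed": s.or_observed,
        "ci_lower": s.ci_lower,
        "ci_upper": s.ci_upper,
        "ci_level": s.ci_level,
        "ci_defined": s.ci_defined,
        "fisher_p": s.fisher_p,
        "acmg2015_verdict": s.acmg2015_verdict.value,
    }
    d["lr"] = {
        "lr": r.lr,
        "log_lr": r.log_lr,
        "ep": r.ep,
        "strength": r.strength.value,
        "lr_display": format_lr(r.lr, log_lr=r.log_lr),
        "ep_display": format_ep(r.ep),
    }
    d["regions"] = {
        "p_assoc": r.regions.p_assoc,
        "p_nonassoc": r.regions.p_nonassoc,
        "area_assoc": r.regions.area_assoc,
        "area_nonassoc": r.regions.area_nonassoc,
        "area_total": r.regions.area_total,
        "occupancy": r.regions.occupancy,
    }
    d["warnings"] = sorted(r.warnings.active)
    d["occupancy"] = r.warnings.occupancy_value
    return d


RESULT_COLUMNS = (
    "label",
    "case_carriers",
    "case_total",
    "control_carriers",
    "control_total",
    "or_assoc",
    "or_nonassoc",
    "or_observed",
    "ci_lower",
    "ci_upper",
    "fisher_p",
    "acmg2015_verdict",
    "lr",
    "log_lr",
    "ep",
    "lr_display",
    "ep_display",
    "strength",
    "occupancy",
    "warnings",
    "error",
)


def results_to_tsv(rows: Iterable[BatchResultRow], stream: IO[str]) -> None:
    """Write one TSV row per record: full-precision numeric columns plus
    display-rounded LR/EP columns; errors land in the ``error`` column."""
    writer = csv.DictWriter(stream, fieldnames=RESULT_COLUMNS, delimiter="\t")
    writer.writeheader()
    for row in rows:
        out = {col: MISSING for col in RESULT_COLUMNS}
        out["label"] = row.label
        if row.record is not None:
            c, t = row.record.counts, row.record.targets
            out.update(
                case_carriers=c.case_carriers,
                case_total=c.case_total,
                control_carriers=c.control_carriers,
                control_total=c.control_total,
                or_assoc=_FULL % t.or_assoc,
                or_nonassoc=_FULL % t.or_nonassoc,
            )
        if row.error is not None:
            out["error"] = row.error
        else:
            r, s = row.result, row.summary
            out.update(
                or_observed=_FULL % s.or_observed,
                ci_lower=_FULL % s.ci_lower,
                ci_upper=_FULL % s.ci_upper,
                fisher_p=_FULL % s.fisher_p,
                acmg2015_verdict=s.acmg2015_verdict.value,
                lr=_FULL % r.lr,
                log_lr=_FULL % r.log_lr,
                ep=_FULL % r.ep,
                lr_display=format_lr(r.lr, log_lr=r.log_lr),
                ep_display=format_ep(r.ep),
                strength=r.strength.value,
                occupancy=_FULL % r.regions.occupancy,
                warnings=",".join(sorted(r.warnings.active)) or MISSING,
            )
        writer.writerow(out)


def results_to_json(rows: Iterable[BatchResultRow], stream: IO[str]) -> None:
    json.dump([_row_dict(row) for row in rows], stream, indent=2, allow_nan=True)
    stream.write("\n")


# ---------------------------------------------------------------------------
# Likelihood-curve export


@dataclass(frozen=True)
class CurveExport:
    """Binomial likelihood curve on a uniform grid, for external plotting.

    ``likelihood`` includes the binomial coefficient, so the curve integrates
    to ``1/(n+1)`` over [0, 1].  The two probability thresholds are carried
    as markers.
    """

    grid: np.ndarray
    likelihood: np.ndarray
    p_assoc: float
    p_nonassoc: float


def export_curve(
    counts: CaseControlCounts, targets: TargetORPair | None = None, n_points: int = 1001
) -> CurveExport:
    """Evaluate the likelihood curve for a scenario on a uniform grid."""
    if n_points < 2:
        raise Ps4lrError("n_points must be >= 2")
    targets = targets if targets is not None else TargetORPair()
    n = counts.carrier_total
    if n < 1:
        raise Ps4lrError("no variant observations: carrier total is zero")
    k = counts.case_carriers
    odds = core.background_case_odds(counts)
    grid = np.linspace(0.0, 1.0, n_points)
    log_coef = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lik = log_coef + k * np.log(grid) + (n - k) * np.log1p(-grid)
    # endpoint conventions: p^0 = 1 even at p = 0, (1-p)^0 = 1 at p = 1
    if k == 0:
        log_lik[0] = log_coef
    if k == n:
        log_lik[-1] = log_coef
    likelihood = np.exp(log_lik)
    likelihood[np.isnan(likelihood)] = 0.0
    return CurveExport(
        grid=grid,
        likelihood=likelihood,
        p_assoc=core.probability_under_or(odds, targets.or_assoc),
        p_nonassoc=core.probability_under_or(odds, targets.or_nonassoc),
    )


def write_curve_tsv(curve: CurveExport, stream: IO[str]) -> None:
    stream.write(f"# p_assoc\t{_FULL % curve.p_assoc}\n")
    stream.write(f"# p_nonassoc\t{_FULL % curve.p_nonassoc}\n")
    stream.write("p\tlikelihood\n")
    for p, lik in zip(curve.grid, curve.likelihood):
        stream.write(f"{_FULL % p}\t{_FULL % lik}\n")
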