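"""Omission-prevalence, co-occurrence and tool-effectiveness statistics.

The analyses here answer three questions about a registry cohort:

1. How often is an empty index field (radiation start date) a true omission
   error rather than genuinely missing data — determined by a manual review
   that either recovers the value (error) or not (truly missing)?
2. Do omission errors cluster?  Records whose index field was erroneously
   omitted are compared with truly-missing and complete records on the
   prevalence of missingness in probe fields (gender, birth date, cancer
   site), with exact binomial confidence intervals and Fisher's exact test.
3. Did reviewing the record summary help?  From access/edit traces, records
   where the summary was opened are compared with the rest on the frequency
   of correcting an omitted target field, with corrections attributed to an
   access when they follow it within a configurable window (default 10 min).

Proportions use exact (Clopper-Pearson) intervals; association tests are
two-sided Fisher exact tests; families of p-values can be adjusted with the
Simes-Hochberg step-up procedure.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .records import EventType, FieldState, PatientRecord

__all__ = [
    "RecordCategory",
    "TraceEvent",
    "FieldStats",
    "CategoryRow",
    "CoOccurrenceTable",
    "EffectivenessResult",
    "UtilizationSummary",
    "classify_records",
    "clopper_pearson_ci",
    "fisher_exact_2x2",
    "hochberg_adjust",
    "cooccurrence_analysis",
    "effectiveness_analysis",
    "utilization_summary",
    "read_traces",
    "write_traces",
    "round_half_up",
    "percent",
]

log = logging.getLogger(__name__)


class RecordCategory(str, enum.Enum):
    """Index-field status after manual review.

    ``no_missing_index`` — the index field was recorded;
    ``missing_not_found`` — empty, and review could not recover a value
    (genuinely missing, no data error);
    ``missing_found`` — empty, but review recovered the value (omission error).
    """

    NO_MISSING_INDEX = "no_missing_index"
    MISSING_NOT_FOUND = "missing_not_found"
    MISSING_FOUND = "missing_found"


@dataclass(frozen=True)
class TraceEvent:
    """A summary-access or field-edit event from the usage log."""

    kind: str  # "summary_access" | "field_edit"
    record_id: str
    user_id: str
    timestamp: dt.datetime
    field: str = ""
    before: str = ""
    after: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("summary_access", "field_edit"):
            raise ValueError(f"unknown trace kind {self.kind!r}")
        if self.kind == "field_edit" and not self.field:
            raise ValueError("field_edit trace requires a field name")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for percents)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(x: int, n: int) -> float:
    return 100.0 * x / n if n else float("nan")


# ---------------------------------------------------------------------------
# core statistics

def clopper_pearson_ci(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial CI, returned in percent.

    Obtained by inverting the binomial tail probabilities (beta quantiles);
    the lower bound is exactly 0 when ``x == 0`` and the upper exactly 100
    when ``x == n``.
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("x and n must be integers")
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"require 0 <= x <= n and n >= 1, got x={x}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    lo, hi = proportion_confint(x, n, alpha=alpha, method="beta")
    return 100.0 * lo, 100.0 * hi


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's (the probability-mass method, not doubling of the one-sided p).
    A zero margin makes the table degenerate: p = 1.0 by convention.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("table entries must be non-negative integers")
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        log.warning("degenerate 2x2 table (zero margin): p = 1.0 by convention")
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def hochberg_adjust(pvalues: Sequence[float]) -> list[float]:
    """Simes-Hochberg step-up adjusted p-values, in input order.

    With the raw p-values sorted in decreasing order p_(1) >= ... >= p_(m),
    the adjusted value for p_(i) is min over j <= i of (j)-th multiplier
    (m - j + 1) * p_(j), clipped at 1; adjustment is monotone in the raw p.
    """
    ps = list(pvalues)
    if not ps:
        return []
    if any(not 0 <= p <= 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="simes-hochberg")[1])


# ---------------------------------------------------------------------------
# record classification and co-occurrence

def _index_missing(record: PatientRecord, index_field: str) -> bool:
    if index_field == "xrt_start":
        return not record.events_of(EventType.XRT_START)
    return getattr(record, index_field).state is not FieldState.PRESENT


def _probe_missing(record: PatientRecord, probe_field: str) -> bool:
    return getattr(record, probe_field).state is FieldState.UNKNOWN


def classify_records(
    records: Sequence[PatientRecord],
    index_field: str = "xrt_start",
    review_results: Mapping[str, bool] | None = None,
) -> dict[str, RecordCategory]:
    """Assign each record its index-field category.

    ``review_results`` maps record id → whether manual review recovered the
    index value, and must cover exactly the records whose index field is
    missing; a review result for a record with a present index field is a
    hard error, as is a missing-index record without one.
    """
    review_results = dict(review_results or {})
    out: dict[str, RecordCategory] = {}
    for rec in records:
        if _index_missing(rec, index_field):
            if rec.record_id not in review_results:
                raise ValueError(
                    f"record {rec.record_id!r} has missing {index_field} but no review result"
                )
            found = review_results.pop(rec.record_id)
            out[rec.record_id] = (
                RecordCategory.MISSING_FOUND if found else RecordCategory.MISSING_NOT_FOUND
            )
        else:
            out[rec.record_id] = RecordCategory.NO_MISSING_INDEX
    if review_results:
        extra = sorted(review_results)[:3]
        raise ValueError(
            f"review results supplied for records whose {index_field} is present: {extra}"
        )
    return out


@dataclass(frozen=True)
class FieldStats:
    missing: int
    percent: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class CategoryRow:
    n: int
    fields: dict[str, FieldStats]
    any_missing: FieldStats | None


@dataclass(frozen=True)
class CoOccurrenceTable:
    rows: dict[RecordCategory, CategoryRow]
    pvalues: dict[str, float]
    pvalues_adjusted: dict[str, float]
    alpha: float

    def to_tsv(self, display_decimals: int = 1) -> str:
        """Prevalence table: category x probe field, `N (%, CI)` cells."""
        fields = list(self.pvalues)
        lines = ["category\tn\t" + "\t".join(f"missing_{f}" for f in fields) + "\tany_missing"]
        for cat in RecordCategory:
            row = self.rows.get(cat)
            if row is None:
                continue
            cells = [cat.value, str(row.n)]
            for f in fields:
                cells.append(_format_cell(row.fields.get(f), display_decimals))
            cells.append(_format_cell(row.any_missing, display_decimals))
            lines.append("\t".join(cells))
        lines.append(
            "fisher_p\t\t"
            + "\t".join(f"{self.pvalues[f]:.4g}" for f in fields)
            + "\t"
        )
        lines.append(
            "fisher_p_adjusted\t\t"
            + "\t".join(f"{self.pvalues_adjusted[f]:.4g}" for f in fields)
            + "\t"
        )
        return "\n".join(lines) + "\n"


def _format_cell(fs: FieldStats | None, nd: int) -> str:
    if fs is None or math.isnan(fs.percent):
        return "-"
    return (
        f"{fs.missing} ({round_half_up(fs.percent, nd)}; "
        f"{round_half_up(fs.ci_low, nd)}-{round_half_up(fs.ci_high, nd)})"
    )


def _field_stats(x: int, n: int, alpha: float) -> FieldStats:
    if n == 0:
        return FieldStats(0, float("nan"), float("nan"), float("nan"))
    lo, hi = clopper_pearson_ci(x, n, alpha)
    return FieldStats(x, percent(x, n), lo, hi)


def cooccurrence_analysis(
    records: Sequence[PatientRecord],
    index_field: str = "xrt_start",
    review_results: Mapping[str, bool] | None = None,
    probe_fields: Sequence[str] = ("gender", "dob", "cancer_site"),
    alpha: float = 0.05,
) -> CoOccurrenceTable:
    """Prevalence and co-occurrence of probe-field missingness by category.

    For every category and probe field: missing count, raw percent and exact
    binomial CI (display rounding is applied only at formatting time).  The
    per-field Fisher p compares the two missing-index categories (truly
    missing vs omission error); the family is also reported Simes-Hochberg
    adjusted.  The any-of-probe-fields missing rate is reported per category.
    """
    categories = classify_records(records, index_field, review_results)
    by_cat: dict[RecordCategory, list[PatientRecord]] = {c: [] for c in RecordCategory}
    for rec in records:
        by_cat[categories[rec.record_id]].append(rec)

    rows: dict[RecordCategory, CategoryRow] = {}
    for cat, recs in by_cat.items():
        n = len(recs)
        fields = {
            f: _field_stats(sum(_probe_missing(r, f) for r in recs), n, alpha)
            for f in probe_fields
        }
        any_x = sum(any(_probe_missing(r, f) for f in probe_fields) for r in recs)
        rows[cat] = CategoryRow(
            n=n,
            fields=fields,
            any_missing=_field_stats(any_x, n, alpha) if n else None,
        )

    b = rows[RecordCategory.MISSING_NOT_FOUND]
    c = rows[RecordCategory.MISSING_FOUND]
    pvalues: dict[str, float] = {}
    for f in probe_fields:
        table = [
            [b.fields[f].missing, b.n - b.fields[f].missing],
            [c.fields[f].missing, c.n - c.fields[f].missing],
        ]
        pvalues[f] = fisher_exact_2x2(table)
    adjusted = dict(zip(pvalues, hochberg_adjust(list(pvalues.values()))))
    return CoOccurrenceTable(rows=rows, pvalues=pvalues, pvalues_adjusted=adjusted, alpha=alpha)


# ---------------------------------------------------------------------------
# traces

_TRACE_COLUMNS = ["kind", "record_id", "user_id", "timestamp", "field", "before", "after"]


def read_traces(path: str | Path) -> list[TraceEvent]:
    out: list[TraceEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TraceEvent(
                    kind=row["kind"],
                    record_id=row["record_id"],
                    user_id=row["user_id"],
                    timestamp=dt.datetime.fromisoformat(row["timestamp"]),
                    field=row.get("field", "") or "",
                    before=row.get("before", "") or "",
                    after=row.get("after", "") or "",
                )
            )
    return out


def write_traces(traces: Iterable[TraceEvent], path: str | Path) -> int:
    n = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TRACE_COLUMNS)
        writer.writeheader()
        for t in traces:
            writer.writerow(
                {
                    "kind": t.kind,
                    "record_id": t.record_id,
                    "user_id": t.user_id,
                    "timestamp": t.timestamp.isoformat(),
                    "field": t.field,
                    "before": t.before,
                    "after": t.after,
                }
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# effectiveness

#: Edit "before" strings that count as a missing state for correction
#: detection (empty cell or the explicit unknown marker).
_MISSING_BEFORE = ("", "UNKNOWN")


@dataclass(frozen=True)
class EffectivenessResult:
    """Accessed-vs-not × corrected-vs-not contingency with attribution."""

    contingency: tuple[tuple[int, int], tuple[int, int]]
    n_accessed: int
    n_not_accessed: int
    corrected_accessed: int
    corrected_not_accessed: int
    prop_accessed: FieldStats
    prop_not_accessed: FieldStats
    fisher_p: float
    window_attributed: int
    window_minutes: float
    revisions: int  # edits overwriting an already-present value


def effectiveness_analysis(
    records: Sequence[PatientRecord],
    traces: Sequence[TraceEvent],
    target_field: str = "relapse_date",
    window_minutes: float = 10.0,
    alpha: float = 0.05,
) -> EffectivenessResult:
    """Compare correction frequency between summary-accessed and other records.

    A record is *accessed* when at least one summary-access trace exists for
    it, and *corrected* when a field edit changed ``target_field`` from a
    missing state (empty / unknown marker) to a present value; edits that
    overwrite an already-present value are counted separately as revisions,
    and no-op edits (before == after) are ignored with a warning.
    ``window_attributed`` counts corrected-and-accessed records whose earliest
    qualifying edit falls within ``window_minutes`` after the latest
    preceding access.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    known_ids = {r.record_id for r in records}
    for t in traces:
        if t.record_id not in known_ids:
            raise ValueError(f"trace references unknown record {t.record_id!r}")

    accesses: dict[str, list[dt.datetime]] = {}
    corrections: dict[str, list[dt.datetime]] = {}
    revisions = 0
    for t in sorted(traces, key=lambda t: (t.timestamp, t.record_id, t.kind)):
        if t.kind == "summary_access":
            accesses.setdefault(t.record_id, []).append(t.timestamp)
        elif t.field == target_field:
            if t.before == t.after:
                log.warning("ignoring no-op edit on %s for %s", t.field, t.record_id)
                continue
            if t.before in _MISSING_BEFORE and t.after not in _MISSING_BEFORE and t.after:
                corrections.setdefault(t.record_id, []).append(t.timestamp)
            elif t.before not in _MISSING_BEFORE:
                revisions += 1

    accessed = {rid for rid in accesses}
    corrected = {rid for rid in corrections}
    n_acc = sum(1 for r in records if r.record_id in accessed)
    n_not = len(records) - n_acc
    corr_acc = sum(1 for r in records if r.record_id in accessed and r.record_id in corrected)
    corr_not = len(corrected & known_ids) - corr_acc

    window = dt.timedelta(minutes=window_minutes)
    attributed = 0
    for rid in corrected & accessed:
        first_edit = min(corrections[rid])
        prior = [a for a in accesses[rid] if a <= first_edit]
        if prior and first_edit - max(prior) <= window:
            attributed += 1

    table = ((corr_acc, n_acc - corr_acc), (corr_not, n_not - corr_not))
    fisher_p = fisher_exact_2x2(table) if (n_acc and n_not) else 1.0
    if not accessed:
        fisher_p = 1.0
    return EffectivenessResult(
        contingency=table,
        n_accessed=n_acc,
        n_not_accessed=n_not,
        corrected_accessed=corr_acc,
        corrected_not_accessed=corr_not,
        prop_accessed=_field_stats(corr_acc, n_acc, alpha),
        prop_not_accessed=_field_stats(corr_not, n_not, alpha),
        fisher_p=fisher_p,
        window_attributed=attributed,
        window_minutes=window_minutes,
        revisions=revisions,
    )


# ---------------------------------------------------------------------------
# utilization

@dataclass(frozen=True)
class UtilizationSummary:
    """Summary-access utilization across a cohort."""

    histogram: dict[str, int]  # access count per record: "0", "1", "2", "3+"
    overall_rate: float  # percent of records with >= 1 access
    new_rate: float  # percent among new records
    update_rate: float  # percent among updated records
    per_user: dict[str, tuple[int, float]]  # user -> (records touched, access rate %)


def utilization_summary(
    records: Sequence[PatientRecord], traces: Sequence[TraceEvent]
) -> UtilizationSummary:
    """Access-count histogram and access rates overall, by entry mode, by user.

    A user's rate is computed over the records that user touched (appeared in
    any trace for): the share of those records where the user opened the
    summary at least once.
    """
    counts = {r.record_id: 0 for r in records}
    touched: dict[str, set[str]] = {}
    user_accessed: dict[str, set[str]] = {}
    for t in traces:
        if t.record_id in counts:
            touched.setdefault(t.user_id, set()).add(t.record_id)
            if t.kind == "summary_access":
                counts[t.record_id] += 1
                user_accessed.setdefault(t.user_id, set()).add(t.record_id)

    hist = {"0": 0, "1": 0, "2": 0, "3+": 0}
    for c in counts.values():
        hist[str(c) if c < 3 else "3+"] += 1

    def rate(recs: list[PatientRecord]) -> float:
        if not recs:
            return 0.0
        return percent(sum(1 for r in recs if counts[r.record_id] > 0), len(recs))

    new = [r for r in records if r.is_new]
    upd = [r for r in records if not r.is_new]
    per_user = {
        u: (len(recs), percent(len(user_accessed.get(u, set())), len(recs)))
        for u, recs in sorted(touched.items())
    }
    return UtilizationSummary(
        histogram=hist,
        overall_rate=rate(list(records)),
        new_rate=rate(new),
        update_rate=rate(upd),
        per_user=per_user,
    )
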