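"""Render the three-section record summary: key fields, timeline, possible errors.

The summary is a read-only document meant to be reviewed at the end of a data
entry session: a verbatim listing of the key demographic/clinical fields, a
schematic timeline of the clinical course with long quiet intervals called
out, and the list of likely (non-certain) errors the rule engine flagged.
Output is deterministic: identical inputs yield identical bytes.
"""

from __future__ import annotations

import html

from .records import PatientRecord, Timeline, build_timeline
from .rules import PossibleError

__all__ = [
    "DEFAULT_KEY_FIELDS",
    "render_summary",
    "render_timeline_text",
    "SECTION_HEADERS",
]

#: Field order for the verbatim key-field section.
DEFAULT_KEY_FIELDS = (
    "record_id",
    "gender",
    "dob",
    "cancer_site",
    "diagnosis_date",
    "tumor_grade",
    "t_stage",
    "vital_status",
    "relapse_date",
)

SECTION_HEADERS = ("== Key Fields ==", "== Timeline ==", "== Possible Errors ==")

_PLACEHOLDERS = ("(no key fields)", "(no dated events)", "(no possible errors)")


def _field_display(record: PatientRecord, name: str) -> str:
    if name == "record_id":
        return record.record_id
    if name == "vital_status":
        return record.vital_status.value
    if name == "remission_documented":
        return "yes" if record.remission_documented else "no"
    return getattr(record, name).render()


def render_timeline_text(timeline: Timeline, width: int = 72) -> list[str]:
    """One line per entry (``YYYY-MM-DD  LABEL``); gaps interleaved.

    A gap between consecutive entries is rendered as an interstitial
    ``── gap: N days ──`` line at the position where the quiet interval falls.
    """
    if width < 40:
        raise ValueError("width must be >= 40")
    if not timeline.entries:
        return [_PLACEHOLDERS[1]]
    gap_after = {g.start: g for g in timeline.gaps}
    lines: list[str] = []
    for i, entry in enumerate(timeline.entries):
        lines.append(f"{entry.date.isoformat()}  {entry.label}"[:width])
        nxt = timeline.entries[i + 1] if i + 1 < len(timeline.entries) else None
        gap = gap_after.get(entry.date)
        if gap is not None and nxt is not None and nxt.date == gap.end:
            text = f" gap: {gap.span_days} days "
            pad = max(0, min(width, 40) - len(text)) // 2
            lines.append("─" * pad + text + "─" * pad)
            gap_after.pop(entry.date)
    return lines


def _render_text(
    record: PatientRecord,
    errors: list[PossibleError],
    key_field_spec: tuple[str, ...],
    gap_threshold_days: int,
) -> str:
    timeline = build_timeline(record, gap_threshold_days)
    out: list[str] = [SECTION_HEADERS[0]]
    if key_field_spec:
        pad = max(len(f) for f in key_field_spec)
        for name in key_field_spec:
            out.append(f"{name.ljust(pad)}  {_field_display(record, name)}")
    else:
        out.append(_PLACEHOLDERS[0])
    out.append("")
    out.append(SECTION_HEADERS[1])
    out.extend(render_timeline_text(timeline))
    out.append("")
    out.append(SECTION_HEADERS[2])
    if errors:
        for err in errors:
            out.append(f"[{err.rule_id}] {err.message}")
            out.append(f"      fields: {', '.join(err.implicated_fields)}")
    else:
        out.append(_PLACEHOLDERS[2])
    out.append("")
    return "\n".join(out)


_HTML_PAGE = """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"><title>Record summary: {record_id}</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
h2 {{ border-bottom: 1px solid #999; }}
table {{ border-collapse: collapse; }}
td {{ padding: 2px 10px; }}
.missing {{ color: #b00; font-weight: bold; }}
.gap {{ color: #666; font-style: italic; }}
.error {{ background: #fff3f3; border-left: 4px solid #b00; padding: 4px 8px; margin: 4px 0; }}
</style></head>
<body>
<h1>Record summary: {record_id}</h1>
<h2>Key Fields</h2>
{key_fields}
<h2>Timeline</h2>
{timeline}
<h2>Possible Errors</h2>
{errors}
</body>
</html>
"""


def _render_html(
    record: PatientRecord,
    errors: list[PossibleError],
    key_field_spec: tuple[str, ...],
    gap_threshold_days: int,
) -> str:
    timeline = build_timeline(record, gap_threshold_days)
    if key_field_spec:
        rows = []
        for name in key_field_spec:
            value = _field_display(record, name)
            cls = ' class="missing"' if value in ("UNKNOWN", "N/A") else ""
            rows.append(
                f"<tr><td>{html.escape(name)}</td>"
                f"<td{cls}>{html.escape(value)}</td></tr>"
            )
        key_html = "<table>\n" + "\n".join(rows) + "\n</table>"
    else:
        key_html = f"<p>{_PLACEHOLDERS[0]}</p>"

    if timeline.entries:
        items = []
        gap_after = {g.start: g for g in timeline.gaps}
        for i, entry in enumerate(timeline.entries):
            items.append(
                f"<li>{entry.date.isoformat()} &mdash; {html.escape(entry.label)}</li>"
            )
            nxt = timeline.entries[i + 1] if i + 1 < len(timeline.entries) else None
            gap = gap_after.get(entry.date)
            if gap is not None and nxt is not None and nxt.date == gap.end:
                items.append(f'<li class="gap">gap: {gap.span_days} days</li>')
                gap_after.pop(entry.date)
        tl_html = "<ul>\n" + "\n".join(items) + "\n</ul>"
    else:
        tl_html = f"<p>{_PLACEHOLDERS[1]}</p>"

    if errors:
        err_html = "\n".join(
            f'<div class="error">[{html.escape(e.rule_id)}] {html.escape(e.message)}'
            f"<br><small>fields: {html.escape(', '.join(e.implicated_fields))}</small></div>"
            for e in errors
        )
    else:
        err_html = f"<p>{_PLACEHOLDERS[2]}</p>"

    return _HTML_PAGE.format(
        record_id=html.escape(record.record_id),
        key_fields=key_html,
        timeline=tl_html,
        errors=err_html,
    )


def render_summary(
    record: PatientRecord,
    errors: list[PossibleError],
    format: str = "text",
    key_field_spec: tuple[str, ...] = DEFAULT_KEY_FIELDS,
    gap_threshold_days: int = 365,
) -> str:
    """Produce the three-section summary document for one record.

    All three sections are always present (empty ones show a placeholder).
    ``errors`` must have been produced from the same record; a mismatched
    record id is a hard error.
    """
    for err in errors:
        if err.record_id != record.record_id:
            raise ValueError(
                f"error for record {err.record_id!r} passed with record "
                f"{record.record_id!r}"
            )
    if format == "text":
        return _render_text(record, errors, tuple(key_field_spec), gap_threshold_days)
    if format == "html":
        return _render_html(record, errors, tuple(key_field_spec), gap_threshold_days)
    raise ValueError(f"unknown format {format!r}")
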