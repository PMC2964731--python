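"""Configurable cross-field "possible error" rules.

Each rule inspects one patient record for a pattern that likely — but not
certainly — indicates an omitted piece of information: treatment activity
that only makes sense after an undocumented relapse, a radiation course cut
short with no recorded toxicity, or a key field left empty.  Firings are
advisory; nothing here blocks data entry.

Rules are registered in a dispatch table keyed by rule id, so new rules can
be added (and enabled from the config file) without touching the engine.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import yaml

from .records import (
    EVENT_TIE_PRIORITY,
    ClinicalEvent,
    EventType,
    FieldState,
    PatientRecord,
    VitalStatus,
)

__all__ = [
    "PossibleError",
    "RuleConfig",
    "RuleConfigError",
    "SurgeryRadicalityTable",
    "DEFAULT_RADICALITY",
    "DEFAULT_PARAMS",
    "RULES",
    "register_rule",
    "apply_rules",
    "default_configs",
    "load_rule_config",
    "rule_R1_escalated_surgery",
    "rule_R2_death_without_relapse",
    "rule_R3_unexpected_treatment",
    "rule_R4_abrupt_xrt_stop",
    "rule_R5_missing_key_fields",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PossibleError:
    """One rule firing: likely error, surfaced non-interruptively."""

    rule_id: str
    record_id: str
    implicated_fields: tuple[str, ...]
    message: str
    certainty: str = "possible"
    #: date of the implicated event, used only for deterministic ordering
    event_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.implicated_fields:
            raise ValueError("implicated_fields must be non-empty")
        if not self.message:
            raise ValueError("message must be non-empty")


@dataclass(frozen=True)
class RuleConfig:
    rule_id: str
    enabled: bool = True
    params: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.params, dict):
            object.__setattr__(self, "params", tuple(sorted(self.params.items())))

    @property
    def param_map(self) -> dict[str, object]:
        return dict(self.params)


class RuleConfigError(Exception):
    """Malformed rule configuration (unknown rule id or invalid parameter)."""


class SurgeryRadicalityTable:
    """Total order over surgical procedure codes, from least to most radical.

    Rules comparing two surgeries skip procedure codes absent from the table
    (they are incomparable, not errors).
    """

    def __init__(self, ranks: Mapping[str, int]):
        if len(set(ranks.values())) != len(ranks):
            raise ValueError("radicality ranks must form a total order (distinct ranks)")
        self._ranks = dict(ranks)

    def rank(self, code: str) -> int | None:
        return self._ranks.get(code)

    def __contains__(self, code: str) -> bool:
        return code in self._ranks

    def as_dict(self) -> dict[str, int]:
        return dict(self._ranks)


#: Default (breast) table; override per cancer site via the config file.
DEFAULT_RADICALITY = SurgeryRadicalityTable(
    {
        "biopsy": 0,
        "lumpectomy": 1,
        "simple_mastectomy": 2,
        "modified_radical_mastectomy": 3,
        "radical_mastectomy": 4,
    }
)

DEFAULT_PARAMS: dict[str, dict[str, object]] = {
    "R1": {"min_gap_days": 30},
    "R2": {},
    "R3": {"quiescence_days": 180},
    "R4": {"min_completion_fraction": 0.8},
    "R5": {"key_fields": ["gender", "dob", "cancer_site", "xrt_start"]},
}

_R5_ALLOWED = {"gender", "dob", "cancer_site", "diagnosis_date", "xrt_start"}

RuleFn = Callable[..., list[PossibleError]]
RULES: dict[str, RuleFn] = {}


def register_rule(rule_id: str) -> Callable[[RuleFn], RuleFn]:
    def deco(fn: RuleFn) -> RuleFn:
        RULES[rule_id] = fn
        return fn

    return deco


# ---------------------------------------------------------------------------
# helpers

def _relapse_dates(record: PatientRecord) -> list[dt.date]:
    dates = [e.date for e in record.events if e.event_type is EventType.RELAPSE]
    if record.relapse_date.is_present:
        dates.append(record.relapse_date.value)
    return sorted(set(dates))


def _relapse_in(record: PatientRecord, after: dt.date, through: dt.date) -> bool:
    """True if a relapse is documented in the half-open interval (after, through]."""
    return any(after < d <= through for d in _relapse_dates(record))


def _match_courses(
    record: PatientRecord, start_t: EventType, end_t: EventType
) -> list[tuple[ClinicalEvent, ClinicalEvent | None]]:
    """Pair each start event with the earliest unconsumed end event at or after it."""
    starts = record.events_of(start_t)
    ends = record.events_of(end_t)
    out: list[tuple[ClinicalEvent, ClinicalEvent | None]] = []
    used = 0
    for s in starts:
        match = None
        while used < len(ends):
            if ends[used].date >= s.date:
                match = ends[used]
                used += 1
                break
            used += 1
        out.append((s, match))
    return out


def _treatment_episodes(record: PatientRecord) -> list[tuple[ClinicalEvent, dt.date]]:
    """(start event, episode end date) for every treatment episode.

    A surgery is a one-day episode; a radiation or chemotherapy course ends at
    its matched end event, or at its start date when no end is recorded.
    """
    episodes: list[tuple[ClinicalEvent, dt.date]] = []
    for ev in record.events_of(EventType.SURGERY):
        episodes.append((ev, ev.date))
    for start_t, end_t in (
        (EventType.XRT_START, EventType.XRT_END),
        (EventType.CHEMO_START, EventType.CHEMO_END),
    ):
        for s, e in _match_courses(record, start_t, end_t):
            episodes.append((s, e.date if e is not None else s.date))
    episodes.sort(key=lambda p: (p[0].date, EVENT_TIE_PRIORITY[p[0].event_type.value]))
    return episodes


# ---------------------------------------------------------------------------
# rules

@register_rule("R1")
def rule_R1_escalated_surgery(
    record: PatientRecord,
    radicality: SurgeryRadicalityTable = DEFAULT_RADICALITY,
    min_gap_days: int = 30,
) -> list[PossibleError]:
    """More radical surgery after an earlier one, with no relapse in between.

    A mastectomy following a lumpectomy usually means the cancer recurred; if
    no relapse is documented between the two procedures, the relapse date was
    probably omitted.  Fires at most once per escalated (later) surgery.
    """
    out: list[PossibleError] = []
    surgeries = [
        (ev, radicality.rank(ev.attr_map["procedure_code"]))
        for ev in record.events_of(EventType.SURGERY)
    ]
    surgeries = [(ev, r) for ev, r in surgeries if r is not None]
    for j, (s2, r2) in enumerate(surgeries):
        for s1, r1 in surgeries[:j]:
            if (
                r1 < r2
                and (s2.date - s1.date).days >= min_gap_days
                and not _relapse_in(record, s1.date, s2.date)
            ):
                out.append(
                    PossibleError(
                        rule_id="R1",
                        record_id=record.record_id,
                        implicated_fields=(
                            f"event:surgery:{s2.date.isoformat()}",
                            "relapse_date",
                        ),
                        message=(
                            f"{s2.attr_map['procedure_code']} on {s2.date.isoformat()} "
                            f"escalates {s1.attr_map['procedure_code']} of "
                            f"{s1.date.isoformat()} with no documented relapse in "
                            "between; relapse date may be omitted"
                        ),
                        event_date=s2.date,
                    )
                )
                break
    return out


@register_rule("R2")
def rule_R2_death_without_relapse(record: PatientRecord) -> list[PossibleError]:
    """Documented remission + death from disease, but no relapse date.

    Dying from the disease after a documented remission implies a relapse
    occurred; an empty relapse-date field is then almost certainly an omission.
    """
    if (
        record.remission_documented
        and record.vital_status is VitalStatus.DIED_FROM_DISEASE
        and record.relapse_date.state is not FieldState.PRESENT
    ):
        return [
            PossibleError(
                rule_id="R2",
                record_id=record.record_id,
                implicated_fields=("relapse_date", "vital_status", "remission_documented"),
                message=(
                    "remission documented and vital status is died-from-disease, "
                    "but no relapse date is recorded"
                ),
            )
        ]
    return []


@register_rule("R3")
def rule_R3_unexpected_treatment(
    record: PatientRecord, quiescence_days: int = 180
) -> list[PossibleError]:
    """Treatment resuming after a long quiet period with no relapse documented.

    Chemotherapy years after a mastectomy only makes sense if the cancer came
    back; fires for each treatment start at least ``quiescence_days`` after
    the end of the latest prior treatment episode when no relapse falls in
    the intervening interval.
    """
    out: list[PossibleError] = []
    episodes = _treatment_episodes(record)
    for i, (start_ev, _) in enumerate(episodes):
        prior_ends = [end for s, end in episodes[:i] if end <= start_ev.date]
        if not prior_ends:
            continue
        latest_end = max(prior_ends)
        if (start_ev.date - latest_end).days >= quiescence_days and not _relapse_in(
            record, latest_end, start_ev.date
        ):
            out.append(
                PossibleError(
                    rule_id="R3",
                    record_id=record.record_id,
                    implicated_fields=(
                        f"event:{start_ev.event_type.value}:{start_ev.date.isoformat()}",
                        "relapse_date",
                    ),
                    message=(
                        f"{start_ev.event_type.value} on {start_ev.date.isoformat()} "
                        f"begins {(start_ev.date - latest_end).days} days after the "
                        "last treatment ended, with no relapse documented in between"
                    ),
                    event_date=start_ev.date,
                )
            )
    return out


@register_rule("R4")
def rule_R4_abrupt_xrt_stop(
    record: PatientRecord, min_completion_fraction: float = 0.8
) -> list[PossibleError]:
    """Radiation course ended well short of its planned duration.

    An abruptly discontinued course suggests an undocumented toxicity; fires
    when the actual duration is strictly below ``min_completion_fraction``
    of the planned duration.  Starts without a planned duration are skipped.
    """
    out: list[PossibleError] = []
    for s, e in _match_courses(record, EventType.XRT_START, EventType.XRT_END):
        planned = s.attr_map.get("planned_duration_days")
        if planned is None or e is None:
            continue
        actual = (e.date - s.date).days
        if actual < min_completion_fraction * planned:
            out.append(
                PossibleError(
                    rule_id="R4",
                    record_id=record.record_id,
                    implicated_fields=(
                        f"event:xrt_end:{e.date.isoformat()}",
                        "toxicity_record",
                    ),
                    message=(
                        f"radiation course of {s.date.isoformat()} stopped after "
                        f"{actual} of {planned} planned days; a toxicity record "
                        "may be omitted"
                    ),
                    event_date=e.date,
                )
            )
    return out


@register_rule("R5")
def rule_R5_missing_key_fields(
    record: PatientRecord,
    key_fields: list[str] | tuple[str, ...] = ("gender", "dob", "cancer_site", "xrt_start"),
) -> list[PossibleError]:
    """A key field is unknown (not-applicable values do not fire).

    Gender, birth date and cancer site are recorded for essentially every
    patient, so an *unknown* there is most plausibly an omission error.  The
    pseudo-field ``xrt_start`` flags the absence of any radiation-start event.
    """
    out: list[PossibleError] = []
    for name in key_fields:
        if name == "xrt_start":
            if not record.events_of(EventType.XRT_START):
                out.append(
                    PossibleError(
                        rule_id="R5",
                        record_id=record.record_id,
                        implicated_fields=("xrt_start",),
                        message="no radiation start event recorded",
                    )
                )
        elif getattr(record, name).state is FieldState.UNKNOWN:
            out.append(
                PossibleError(
                    rule_id="R5",
                    record_id=record.record_id,
                    implicated_fields=(name,),
                    message=f"key field {name} is unknown",
                )
            )
    return out


# ---------------------------------------------------------------------------
# engine

def default_configs() -> list[RuleConfig]:
    return [
        RuleConfig(rule_id=rid, enabled=True, params=tuple(sorted(DEFAULT_PARAMS[rid].items())))
        for rid in sorted(RULES)
    ]


def apply_rules(
    record: PatientRecord,
    configs: list[RuleConfig] | None = None,
    radicality: SurgeryRadicalityTable = DEFAULT_RADICALITY,
) -> list[PossibleError]:
    """Run all enabled rules over one record.

    Pure function of its inputs; firings are ordered by (rule id, implicated
    event date).  Rules that cannot evaluate a record (missing prerequisite
    fields, unrankable procedure codes) skip it silently — a skip is logged,
    never flagged.
    """
    if configs is None:
        configs = default_configs()
    out: list[PossibleError] = []
    for cfg in sorted(configs, key=lambda c: c.rule_id):
        if not cfg.enabled:
            continue
        fn = RULES.get(cfg.rule_id)
        if fn is None:
            raise RuleConfigError(f"unknown rule id {cfg.rule_id!r}")
        kwargs = dict(cfg.param_map)
        if cfg.rule_id == "R1":
            kwargs["radicality"] = radicality
        out.extend(fn(record, **kwargs))
    out.sort(key=lambda e: (e.rule_id, e.event_date or dt.date.min, e.implicated_fields))
    return out


# ---------------------------------------------------------------------------
# config loading

def _validate_params(rule_id: str, params: dict[str, object]) -> None:
    schema = DEFAULT_PARAMS.get(rule_id)
    if schema is None:
        return  # user-registered rule: no built-in schema
    for key, value in params.items():
        if key not in schema:
            raise RuleConfigError(f"rule {rule_id}: unknown parameter {key!r}")
        if key in ("min_gap_days", "quiescence_days"):
            if not isinstance(value, int) or value < 0:
                raise RuleConfigError(f"rule {rule_id}: {key} must be a non-negative integer")
        elif key == "min_completion_fraction":
            if not isinstance(value, (int, float)) or not 0 < value <= 1:
                raise RuleConfigError(f"rule {rule_id}: {key} must be in (0, 1]")
        elif key == "key_fields":
            if not isinstance(value, (list, tuple)) or not set(value) <= _R5_ALLOWED:
                raise RuleConfigError(
                    f"rule {rule_id}: key_fields must be a subset of {sorted(_R5_ALLOWED)}"
                )


def load_rule_config(
    path: str | Path,
) -> tuple[list[RuleConfig], SurgeryRadicalityTable]:
    """Load rule configuration from a YAML or JSON file.

    The file may list ``rules: [{id, enabled, params}]`` and a ``radicality``
    code→rank map.  Anything absent falls back to the built-in defaults; an
    empty file enables every built-in rule with its defaults.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if text.strip() else None
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise RuleConfigError("config root must be a mapping")

    radicality = DEFAULT_RADICALITY
    if "radicality" in data:
        table = data["radicality"]
        if not isinstance(table, dict) or not all(
            isinstance(v, int) for v in table.values()
        ):
            raise RuleConfigError("radicality must map procedure codes to integer ranks")
        radicality = SurgeryRadicalityTable(table)

    by_id = {cfg.rule_id: cfg for cfg in default_configs()}
    for entry in data.get("rules", []):
        if not isinstance(entry, dict) or "id" not in entry:
            raise RuleConfigError(f"malformed rule entry: {entry!r}")
        rid = entry["id"]
        if rid not in RULES:
            raise RuleConfigError(f"unknown rule id {rid!r}")
        params = dict(DEFAULT_PARAMS.get(rid, {}))
        user_params = entry.get("params", {})
        if not isinstance(user_params, dict):
            raise RuleConfigError(f"rule {rid}: params must be a mapping")
        _validate_params(rid, user_params)
        params.update(user_params)
        by_id[rid] = RuleConfig(
            rule_id=rid,
            enabled=bool(entry.get("enabled", True)),
            params=tuple(sorted(params.items())),
        )
    return list(by_id.values()), radicality


def errors_to_json(errors: list[PossibleError]) -> str:
    return json.dumps(
        [
            {
                "rule_id": e.rule_id,
                "record_id": e.record_id,
                "implicated_fields": list(e.implicated_fields),
                "message": e.message,
                "certainty": e.certainty,
            }
            for e in errors
        ],
        indent=1,
    )
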