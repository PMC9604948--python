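"""Domain types and readers/writers for per-embryo time-lapse event logs.

An event log is tidy: one row per observed transition, either a cleavage
(the embryo reaches a new blastomere count) or a stage onset (compaction,
cavitation, expansion). Times are hours post-fertilization, with
fertilization (start of gamete co-incubation) as time 0.

File dialects
-------------
CSV (UTF-8, header mandatory) with columns::

    embryo_id, run_id, time_h, event_type, cell_count, symmetry, grade

``event_type`` is one of ``cleavage``, ``morula``, ``early_blastocyst``,
``blastocyst``, ``expanded_blastocyst`` or ``end_of_record`` (an explicit
end-of-observation marker carrying only a time). ``cell_count`` is the
blastomere count *after* a cleavage event and empty otherwise. ``symmetry``
(``equal``/``unequal``) and ``grade`` (``good``/``fair``/``poor``) are
optional annotations on cleavage events.

JSON mirrors this as an array of embryo objects, each with an ``events``
array, plus an optional ``runs`` metadata block (date label, oocyte count)
that the flat CSV cannot carry.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: A record is complete without a stage event only if observation provably
#: ran to the end of the standard 190 h culture window.
FULL_RECORD_HOURS = 190.0

#: Image-acquisition grid of the time-lapse incubator (one frame / 5 min).
TIME_GRID_H = 5.0 / 60.0


class Stage(str, Enum):
    """Developmental milestones recorded by the annotator."""

    CLEAVAGE = "cleavage"
    MORULA = "morula"
    EARLY_BLASTOCYST = "early_blastocyst"
    BLASTOCYST = "blastocyst"
    EXPANDED_BLASTOCYST = "expanded_blastocyst"


#: Developmental order of post-cleavage stages, used for monotonicity checks.
STAGE_ORDER: tuple[Stage, ...] = (
    Stage.MORULA,
    Stage.EARLY_BLASTOCYST,
    Stage.BLASTOCYST,
    Stage.EXPANDED_BLASTOCYST,
)


class Symmetry(str, Enum):
    EQUAL = "equal"
    UNEQUAL = "unequal"
    NOT_APPLICABLE = "not_applicable"


class EventLogError(ValueError):
    """Malformed event-log content; the message names the offending row."""


@dataclass(frozen=True)
class TransitionEvent:
    """One observed transition.

    Parameters
    ----------
    time_h
        Hours post-fertilization, non-negative.
    stage
        ``Stage.CLEAVAGE`` for division events, otherwise the stage whose
        onset this event marks.
    cell_count
        Blastomere count after the event; required for cleavage events,
        ``None`` for stage onsets.
    symmetry
        Blastomere-size symmetry annotation; stage events must carry
        ``NOT_APPLICABLE``.
    grade
        Optional morphology grade (``good``/``fair``/``poor``) assigned at
        this event.
    """

    time_h: float
    stage: Stage
    cell_count: int | None = None
    symmetry: Symmetry = Symmetry.NOT_APPLICABLE
    grade: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise EventLogError(f"time_h must be finite and >= 0, got {self.time_h!r}")
        if self.stage is Stage.CLEAVAGE:
            if self.cell_count is None or self.cell_count < 1:
                raise EventLogError(
                    f"cleavage event at {self.time_h} h needs cell_count >= 1, "
                    f"got {self.cell_count!r}"
                )
        else:
            if self.symmetry is not Symmetry.NOT_APPLICABLE:
                raise EventLogError(
                    f"stage event {self.stage.value!r} must have symmetry "
                    "not_applicable"
                )
        if self.grade is not None and self.grade not in ("good", "fair", "poor"):
            raise EventLogError(f"grade must be good/fair/poor, got {self.grade!r}")

    @property
    def is_cleavage(self) -> bool:
        return self.stage is Stage.CLEAVAGE


@dataclass
class EmbryoRecord:
    """Ordered transition events for one embryo.

    ``complete`` marks records with a full, unambiguous trace. When not set
    explicitly it is derived: a record is complete if it contains at least
    one stage event or its observation window provably ran to
    ``FULL_RECORD_HOURS`` (an ``end_of_record`` marker at >= 190 h).
    """

    embryo_id: str
    run_id: str
    events: list[TransitionEvent] = field(default_factory=list)
    end_of_record_h: float | None = None
    complete: bool | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time_h)
        times = [e.time_h for e in self.events]
        for a, b in zip(times, times[1:]):
            if not a < b:
                raise EventLogError(
                    f"embryo {self.embryo_id!r}: event times must be strictly "
                    f"increasing, found {a} followed by {b}"
                )
        first = next((e for e in self.events if e.is_cleavage), None)
        if first is not None and first.cell_count == 1:
            raise EventLogError(
                f"embryo {self.embryo_id!r}: first cleavage event cannot leave "
                "the embryo at 1 cell (records start from a 1-cell zygote)"
            )
        if self.complete is None:
            self.complete = self._derive_complete()

    def _derive_complete(self) -> bool:
        if any(not e.is_cleavage for e in self.events):
            return True
        return (
            self.end_of_record_h is not None
            and self.end_of_record_h >= FULL_RECORD_HOURS
        )

    @property
    def cleavage_events(self) -> list[TransitionEvent]:
        return [e for e in self.events if e.is_cleavage]

    @property
    def stage_events(self) -> list[TransitionEvent]:
        return [e for e in self.events if not e.is_cleavage]

    @property
    def reached(self) -> frozenset[Stage]:
        """Set of stages attained, consistent with the event list."""
        return frozenset(e.stage for e in self.events)

    @property
    def grades(self) -> dict[str, str]:
        """Morphology grades keyed by milestone.

        Cleavage events are keyed ``"{count}cell"``; stage events by the
        stage name. Later annotations win if a milestone repeats.
        """
        out: dict[str, str] = {}
        for e in self.events:
            if e.grade is None:
                continue
            key = f"{e.cell_count}cell" if e.is_cleavage else e.stage.value
            out[key] = e.grade
        return out


@dataclass
class RunInfo:
    """Metadata for one in-vitro production run."""

    run_id: str
    date_label: str | None = None
    n_oocytes: int | None = None


@dataclass
class Cohort:
    """A set of embryo records grouped into in-vitro production runs."""

    records: list[EmbryoRecord] = field(default_factory=list)
    runs: dict[str, RunInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.records:
            if r.embryo_id in seen:
                raise EventLogError(f"duplicate embryo_id {r.embryo_id!r}")
            seen.add(r.embryo_id)
        for r in self.records:
            self.runs.setdefault(r.run_id, RunInfo(run_id=r.run_id))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def run_ids(self) -> list[str]:
        return list(self.runs)

    def by_run(self) -> dict[str, list[EmbryoRecord]]:
        out: dict[str, list[EmbryoRecord]] = {rid: [] for rid in self.runs}
        for r in self.records:
            out[r.run_id].append(r)
        return out


# ---------------------------------------------------------------------------
# readers / writers

_CSV_COLUMNS = ["embryo_id", "run_id", "time_h", "event_type", "cell_count", "symmetry", "grade"]
_END_MARKER = "end_of_record"


def _parse_time(raw: str, where: str) -> float:
    try:
        t = float(raw)
    except (TypeError, ValueError):
        raise EventLogError(f"{where}: malformed time_h {raw!r}") from None
    if not math.isfinite(t) or t < 0:
        raise EventLogError(f"{where}: time_h must be finite and >= 0, got {raw!r}")
    return t


def _row_to_event(row: Mapping[str, object], where: str) -> TransitionEvent | tuple[str, float]:
    """Parse one tidy row; end_of_record rows return ('end', time)."""
    etype = str(row.get("event_type") or "").strip()
    if not etype:
        raise EventLogError(f"{where}: missing event_type")
    t = _parse_time(str(row.get("time_h", "")), where)
    if etype == _END_MARKER:
        return ("end", t)
    try:
        stage = Stage(etype)
    except ValueError:
        raise EventLogError(f"{where}: unknown event_type {etype!r}") from None
    raw_count = row.get("cell_count")
    count: int | None = None
    if raw_count not in (None, ""):
        try:
            count = int(float(str(raw_count)))
        except (TypeError, ValueError):
            raise EventLogError(f"{where}: malformed cell_count {raw_count!r}") from None
    raw_sym = str(row.get("symmetry") or "").strip()
    sym = Symmetry(raw_sym) if raw_sym else Symmetry.NOT_APPLICABLE
    raw_grade = str(row.get("grade") or "").strip() or None
    try:
        return TransitionEvent(time_h=t, stage=stage, cell_count=count, symmetry=sym, grade=raw_grade)
    except EventLogError as err:
        raise EventLogError(f"{where}: {err}") from None


def _assemble(rows: Iterable[tuple[str, str, TransitionEvent | tuple[str, float]]],
              runs: dict[str, RunInfo] | None = None) -> Cohort:
    by_embryo: dict[str, dict] = {}
    for embryo_id, run_id, ev in rows:
        slot = by_embryo.setdefault(
            embryo_id, {"run_id": run_id, "events": [], "end": None}
        )
        if slot["run_id"] != run_id:
            raise EventLogError(
                f"embryo {embryo_id!r} appears under runs "
                f"{slot['run_id']!r} and {run_id!r}"
            )
        if isinstance(ev, tuple):
            slot["end"] = ev[1]
        else:
            slot["events"].append(ev)
    records = [
        EmbryoRecord(
            embryo_id=eid,
            run_id=slot["run_id"],
            events=slot["events"],
            end_of_record_h=slot["end"],
        )
        for eid, slot in by_embryo.items()
    ]
    return Cohort(records=records, runs=dict(runs or {}))


def read_event_log(path: str | Path, format: str = "csv") -> Cohort:
    """Read an annotation event log into a :class:`Cohort`.

    Rows with missing mandatory fields or malformed values raise
    :class:`EventLogError` naming the offending row; events are returned
    sorted by time within each embryo.
    """
    path = Path(path)
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EventLogError(f"{path}: empty file (header required)")
            missing = set(_CSV_COLUMNS[:4]) - set(reader.fieldnames)
            if missing:
                raise EventLogError(f"{path}: missing columns {sorted(missing)}")
            rows = []
            for i, row in enumerate(reader, start=2):
                where = f"{path.name} row {i}"
                eid = (row.get("embryo_id") or "").strip()
                rid = (row.get("run_id") or "").strip()
                if not eid or not rid:
                    raise EventLogError(f"{where}: missing embryo_id/run_id")
                rows.append((eid, rid, _row_to_event(row, where)))
        return _assemble(rows)
    if format == "json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        if isinstance(payload, dict):
            embryos = payload.get("embryos", [])
            runs = {
                r["run_id"]: RunInfo(
                    run_id=r["run_id"],
                    date_label=r.get("date_label"),
                    n_oocytes=r.get("n_oocytes"),
                )
                for r in payload.get("runs", [])
            }
        else:
            embryos, runs = payload, {}
        rows = []
        for j, emb in enumerate(embryos):
            where = f"{path.name} embryo #{j}"
            eid = emb.get("embryo_id")
            rid = emb.get("run_id")
            if not eid or not rid:
                raise EventLogError(f"{where}: missing embryo_id/run_id")
            for ev in emb.get("events", []):
                rows.append((eid, rid, _row_to_event(ev, f"{where} ({eid})")))
            if emb.get("end_of_record_h") is not None:
                rows.append((eid, rid, ("end", float(emb["end_of_record_h"]))))
        return _assemble(rows, runs)
    raise ValueError(f"unknown format {format!r}")


def _event_to_row(rec: EmbryoRecord, ev: TransitionEvent) -> dict[str, object]:
    return {
        "embryo_id": rec.embryo_id,
        "run_id": rec.run_id,
        "time_h": repr(ev.time_h),
        "event_type": ev.stage.value,
        "cell_count": "" if ev.cell_count is None else ev.cell_count,
        "symmetry": "" if ev.symmetry is Symmetry.NOT_APPLICABLE else ev.symmetry.value,
        "grade": ev.grade or "",
    }


def write_event_log(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort; ``read_event_log`` on the output reproduces it."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for rec in cohort.records:
                for ev in rec.events:
                    writer.writerow(_event_to_row(rec, ev))
                if rec.end_of_record_h is not None:
                    writer.writerow(
                        {
                            "embryo_id": rec.embryo_id,
                            "run_id": rec.run_id,
                            "time_h": repr(rec.end_of_record_h),
                            "event_type": _END_MARKER,
                            "cell_count": "",
                            "symmetry": "",
                            "grade": "",
                        }
                    )
        return
    if format == "json":
        payload = {
            "runs": [
                {
                    "run_id": info.run_id,
                    "date_label": info.date_label,
                    "n_oocytes": info.n_oocytes,
                }
                for info in cohort.runs.values()
            ],
            "embryos": [
                {
                    "embryo_id": rec.embryo_id,
                    "run_id": rec.run_id,
                    "end_of_record_h": rec.end_of_record_h,
                    "events": [
                        {
                            "time_h": ev.time_h,
                            "event_type": ev.stage.value,
                            "cell_count": ev.cell_count,
                            "symmetry": None
                            if ev.symmetry is Symmetry.NOT_APPLICABLE
                            else ev.symmetry.value,
                            "grade": ev.grade,
                        }
                        for ev in rec.events
                    ],
                }
                for rec in cohort.records
            ],
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, indent=1) + "\n", encoding="utf-8"
        )
        return
    raise ValueError(f"unknown format {format!r}")


def filter_complete(cohort: Cohort) -> Cohort:
    """Drop partial or unclear records (``complete == False``), idempotently."""
    kept = [r for r in cohort.records if r.complete]
    n_dropped = len(cohort.records) - len(kept)
    if n_dropped:
        logger.warning("filter_complete: excluded %d incomplete record(s)", n_dropped)
    if not kept and cohort.records:
        logger.warning("filter_complete: no complete records remain")
    kept_runs = {r.run_id for r in kept}
    runs = {rid: info for rid, info in cohort.runs.items() if rid in kept_runs}
    return Cohort(records=[replace(r) for r in kept], runs=runs)
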