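"""Domain types and file I/O for longitudinal coded EHR data.

All dates are integer day indices (days since an arbitrary epoch); calendar
semantics never enter the package.  A patient's record is a list of dated,
coded events in one of four categories (ICD9 diagnoses, CPT procedures,
RXCUI medications, ENCOUNTER visits), plus demographics and an optional
death date.

The on-disk event-log format is a tab-separated text file with two record
kinds distinguished by a leading tag column::

    # palliascreen event log v1
    P<TAB>patient_id<TAB>birth_date<TAB>gender<TAB>race<TAB>ethnicity<TAB>death_date_or_NA
    E<TAB>patient_id<TAB>date<TAB>category<TAB>code<TAB>encounter_type   (last col optional)

Readers return each patient's events in canonical order
(date, category, code, encounter_type), so parsing is insensitive to the
order of rows in the file.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

DAYS_PER_YEAR = 365.25
FIELD_SEP = "\t"


class CodeCategory(enum.Enum):
    """Closed enumeration of clinical code systems."""

    ICD9 = "ICD9"
    CPT = "CPT"
    RXCUI = "RXCUI"
    ENCOUNTER = "ENCOUNTER"


#: Encounter types used throughout the package (the ENCOUNTER "codes").
ENCOUNTER_TYPES = ("INPATIENT", "OUTPATIENT", "ER", "SCAN")

GENDERS = ("MALE", "FEMALE", "OTHER")


class EventLogParseError(ValueError):
    """Malformed row in an event-log file (carries the 1-based line number)."""


class EventLogValidationError(ValueError):
    """Parsed rows violate a population invariant (names the patient)."""


@dataclass(slots=True)
class EventRecord:
    """One dated coded clinical event.

    ``encounter_type`` is present exactly when ``category`` is ENCOUNTER;
    for encounter events ``code`` equals the encounter type.
    """

    patient_id: str
    date: int
    code: str
    category: CodeCategory
    encounter_type: Optional[str] = None

    def sort_key(self) -> tuple:
        return (self.date, self.category.value, self.code, self.encounter_type or "")


@dataclass(slots=True)
class Demographics:
    birth_date: int
    gender: str
    race: str
    ethnicity: str

    def age_at(self, date: int) -> int:
        """Age in whole years at ``date``: floor((date - birth)/365.25)."""
        return int((date - self.birth_date) // DAYS_PER_YEAR)


@dataclass(slots=True)
class PatientRecord:
    patient_id: str
    demographics: Demographics
    events: list = field(default_factory=list)
    death_date: Optional[int] = None

    def first_event_date(self) -> Optional[int]:
        return self.events[0].date if self.events else None

    def last_event_date(self) -> Optional[int]:
        return self.events[-1].date if self.events else None


@dataclass(slots=True)
class Violation:
    """One invariant violation found by :func:`validate_population`."""

    patient_id: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.patient_id}: {self.rule} {self.detail}".rstrip()


def validate_population(patients: Iterable[PatientRecord]) -> list[Violation]:
    """Check every population invariant; violations are returned, not raised.

    Rules checked per patient: events carry the patient's id; dates are
    non-negative and sorted ascending; codes non-empty; encounter_type is
    present iff the category is ENCOUNTER; no event after the death date;
    birth date does not exceed the first event date; gender is one of
    MALE/FEMALE/OTHER.
    """
    violations: list[Violation] = []
    for p in patients:
        add = violations.append
        if p.demographics.gender not in GENDERS:
            add(Violation(p.patient_id, "invalid gender", p.demographics.gender))
        prev = None
        for ev in p.events:
            if ev.patient_id != p.patient_id:
                add(Violation(p.patient_id, "foreign event", ev.patient_id))
            if ev.date < 0:
                add(Violation(p.patient_id, "negative event date", str(ev.date)))
            if prev is not None and ev.date < prev:
                add(Violation(p.patient_id, "events out of order",
                              f"{ev.date} after {prev}"))
            prev = ev.date
            if not ev.code:
                add(Violation(p.patient_id, "empty code", str(ev.date)))
            if (ev.encounter_type is not None) != (ev.category is CodeCategory.ENCOUNTER):
                add(Violation(p.patient_id, "encounter_type mismatch",
                              f"{ev.category.value} at day {ev.date}"))
            if p.death_date is not None and ev.date > p.death_date:
                add(Violation(p.patient_id, "event after death",
                              f"day {ev.date} > death {p.death_date}"))
        if p.events and p.demographics.birth_date > p.events[0].date:
            add(Violation(p.patient_id, "birth after first event",
                          f"{p.demographics.birth_date} > {p.events[0].date}"))
    return violations


def _parse_event_row(cols: list[str], lineno: int) -> EventRecord:
    if len(cols) not in (5, 6):
        raise EventLogParseError(f"line {lineno}: expected 5 or 6 columns, got {len(cols)}")
    _, pid, date_s, cat_s, code = cols[:5]
    try:
        date = int(date_s)
    except ValueError:
        raise EventLogParseError(f"line {lineno}: non-integer date {date_s!r}") from None
    try:
        category = CodeCategory(cat_s)
    except ValueError:
        raise EventLogParseError(f"line {lineno}: unknown category {cat_s!r}") from None
    enc = cols[5] if len(cols) == 6 and cols[5] else None
    if (enc is not None) != (category is CodeCategory.ENCOUNTER):
        raise EventLogParseError(
            f"line {lineno}: encounter_type must be present iff category is ENCOUNTER")
    if not code:
        raise EventLogParseError(f"line {lineno}: empty code")
    return EventRecord(pid, date, code, category, enc)


def read_event_log(path) -> list[PatientRecord]:
    """Parse an event-log file into PatientRecords.

    Returns one record per distinct patient_id, sorted by patient_id, with
    events in canonical order.  Raises :class:`EventLogParseError` for a
    malformed row (naming its line number) and
    :class:`EventLogValidationError` when an event postdates the patient's
    death date.
    """
    demos: dict[str, tuple[Demographics, Optional[int]]] = {}
    events: dict[str, list[EventRecord]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split(FIELD_SEP)
            tag = cols[0]
            if tag == "E":
                ev = _parse_event_row(cols, lineno)
                events.setdefault(ev.patient_id, []).append(ev)
            elif tag == "P":
                if len(cols) != 7:
                    raise EventLogParseError(
                        f"line {lineno}: expected 7 columns in P row, got {len(cols)}")
                _, pid, birth_s, gender, race, ethnicity, death_s = cols
                try:
                    birth = int(birth_s)
                    death = None if death_s == "NA" else int(death_s)
                except ValueError:
                    raise EventLogParseError(
                        f"line {lineno}: non-integer date in P row") from None
                if gender not in GENDERS:
                    raise EventLogParseError(f"line {lineno}: unknown gender {gender!r}")
                demos[pid] = (Demographics(birth, gender, race, ethnicity), death)
            else:
                raise EventLogParseError(f"line {lineno}: unknown row tag {tag!r}")

    missing = sorted(set(events) - set(demos))
    if missing:
        raise EventLogValidationError(
            f"events without a P row for patient(s) {', '.join(missing)}")

    patients = []
    for pid in sorted(demos):
        demo, death = demos[pid]
        evs = sorted(events.get(pid, []), key=EventRecord.sort_key)
        if death is not None and evs and evs[-1].date > death:
            raise EventLogValidationError(
                f"patient {pid}: event at day {evs[-1].date} after death date {death}")
        patients.append(PatientRecord(pid, demo, evs, death))
    return patients


def write_event_log(patients: Iterable[PatientRecord], path) -> None:
    """Write patients to ``path``; inverse of :func:`read_event_log`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# palliascreen event log v1\n")
        for p in sorted(patients, key=lambda p: p.patient_id):
            d = p.demographics
            death = "NA" if p.death_date is None else str(p.death_date)
            fh.write(FIELD_SEP.join(
                ["P", p.patient_id, str(d.birth_date), d.gender, d.race,
                 d.ethnicity, death]) + "\n")
            for ev in p.events:
                cols = ["E", ev.patient_id, str(ev.date), ev.category.value, ev.code]
                if ev.encounter_type is not None:
                    cols.append(ev.encounter_type)
                fh.write(FIELD_SEP.join(cols) + "\n")
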