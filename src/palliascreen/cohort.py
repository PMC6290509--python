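"""Cohort construction: prediction dates, labels, censoring, splits.

A *prediction date* (PD) splits a patient's timeline into an observation
past and a virtual future; the label is death within 365 days after PD.
Dates are chosen under temporal sanity constraints so labels cannot be
invalidated:

positives (patients with a recorded death date)
    PD is a recorded encounter date with
    ``death - 365 <= PD <= death - 90`` and ``PD >= first_event + 365``;
    among feasible dates, dates inside an inpatient admission are preferred,
    then the earliest is taken.

negatives (no death date)
    PD is a recorded encounter date with ``PD >= first_event + 365`` and
    ``PD <= last_event - 365`` (so survival for a full year past PD is
    certain within the record); inpatient dates preferred, then the latest.

If the selected date falls within an inpatient admission the patient is
flagged *admitted* and the date is moved to the admission's second day
(records typically complete within the first 24 h); if the move breaks a
constraint the original date is kept (still flagged admitted).  All events
after the prediction date are censored away.

Interval bounds are inclusive throughout; "3 months" is 90 days and
"12 months" is 365 days.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .ehr import CodeCategory, Demographics, EventRecord, PatientRecord

YEAR = 365
QUARTER = 90


@dataclass(slots=True)
class CohortInstance:
    """One labeled training example: a censored patient history at a PD.

    ``label`` is 1 when the source patient dies within 365 days after the
    prediction date, 0 for a confirmed survivor, and None for unlabeled
    (deployment-time screening) instances.  ``followup_end`` is the last
    event date of the *uncensored* source record, used for censor-length
    curves.
    """

    patient_id: str
    prediction_date: int
    label: Optional[int]
    admitted: bool
    events: list
    demographics: Demographics
    death_date: Optional[int] = None
    followup_end: Optional[int] = None


@dataclass(slots=True)
class CohortSplit:
    train: list
    validation: list
    test: list


def inpatient_spans(patient: PatientRecord) -> list[tuple[int, int]]:
    """Maximal runs of consecutive days with an INPATIENT encounter event,
    as inclusive ``(start, end)`` day pairs."""
    days = sorted({ev.date for ev in patient.events
                   if ev.category is CodeCategory.ENCOUNTER
                   and ev.encounter_type == "INPATIENT"})
    spans = []
    for d in days:
        if spans and d == spans[-1][1] + 1:
            spans[-1][1] = d
        else:
            spans.append([d, d])
    return [tuple(s) for s in spans]


def encounter_dates(patient: PatientRecord) -> list[int]:
    """Sorted distinct dates bearing an ENCOUNTER event."""
    return sorted({ev.date for ev in patient.events
                   if ev.category is CodeCategory.ENCOUNTER})


def candidate_dates_positive(patient: PatientRecord) -> list[int]:
    """Feasible prediction dates for a deceased patient (sorted ascending)."""
    if patient.death_date is None:
        raise ValueError(f"patient {patient.patient_id} has no death date")
    first = patient.first_event_date()
    if first is None:
        return []
    death = patient.death_date
    lo = max(death - YEAR, first + YEAR)
    hi = death - QUARTER
    return [d for d in encounter_dates(patient) if lo <= d <= hi]


def candidate_dates_negative(patient: PatientRecord) -> list[int]:
    """Feasible prediction dates for a surviving patient (sorted ascending)."""
    if patient.death_date is not None:
        raise ValueError(f"patient {patient.patient_id} has a death date")
    first = patient.first_event_date()
    last = patient.last_event_date()
    if first is None:
        return []
    return [d for d in encounter_dates(patient)
            if d >= first + YEAR and d <= last - YEAR]


def _satisfies_case(patient: PatientRecord, d: int) -> bool:
    first = patient.first_event_date()
    if d < first + YEAR:
        return False
    if patient.death_date is not None:
        return patient.death_date - YEAR <= d <= patient.death_date - QUARTER
    return d <= patient.last_event_date() - YEAR


def select_prediction_date(patient: PatientRecord) -> Optional[tuple[int, bool]]:
    """Pick the patient's prediction date, or None when infeasible.

    Restricts to candidates inside an inpatient admission when any exist,
    picks earliest (positive) / latest (negative), then applies the
    second-day-of-admission adjustment with constraint re-verification.
    """
    positive = patient.death_date is not None
    cands = (candidate_dates_positive(patient) if positive
             else candidate_dates_negative(patient))
    if not cands:
        return None
    spans = inpatient_spans(patient)

    def span_of(d: int):
        for s, e in spans:
            if s <= d <= e:
                return (s, e)
        return None

    inpat = [d for d in cands if span_of(d) is not None]
    pool = inpat if inpat else cands
    pick = min(pool) if positive else max(pool)
    span = span_of(pick)
    if span is None:
        return (pick, False)
    second = span[0] + 1
    enc_days = set(encounter_dates(patient))
    if second in enc_days and _satisfies_case(patient, second):
        return (second, True)
    return (pick, True)


def build_cohort(patients: Iterable[PatientRecord],
                 return_exclusions: bool = False):
    """Build one censored, labeled instance per eligible patient.

    Patients with no feasible prediction date are excluded (not an error);
    with ``return_exclusions=True`` a ``(instances, Counter)`` pair is
    returned where the counter tallies exclusion reasons.
    """
    instances: list[CohortInstance] = []
    exclusions: Counter = Counter()
    for p in patients:
        if not p.events:
            exclusions["no_events"] += 1
            continue
        sel = select_prediction_date(p)
        if sel is None:
            exclusions["no_feasible_prediction_date"] += 1
            continue
        pd_, admitted = sel
        label = int(p.death_date is not None and p.death_date - pd_ <= YEAR)
        instances.append(CohortInstance(
            patient_id=p.patient_id,
            prediction_date=pd_,
            label=label,
            admitted=admitted,
            events=[ev for ev in p.events if ev.date <= pd_],
            demographics=p.demographics,
            death_date=p.death_date,
            followup_end=p.last_event_date(),
        ))
    if return_exclusions:
        return instances, exclusions
    return instances


def split_cohort(instances: Sequence[CohortInstance],
                 ratios: tuple = (8, 1, 1),
                 seed: int = 0) -> CohortSplit:
    """Patient-level multinomial split (deterministic given seed)."""
    if min(ratios) < 0 or sum(ratios) <= 0:
        raise ValueError("ratios must be non-negative with positive sum")
    probs = np.asarray(ratios, dtype=float) / sum(ratios)
    ordered = sorted(instances, key=lambda inst: inst.patient_id)
    pids = sorted({inst.patient_id for inst in ordered})
    rng = np.random.default_rng(seed)
    assign = {pid: rng.choice(3, p=probs) for pid in pids}
    parts: list[list] = [[], [], []]
    for inst in ordered:
        parts[assign[inst.patient_id]].append(inst)
    return CohortSplit(*parts)


def censor_length_curve(instances: Sequence[CohortInstance]) -> dict:
    """Empirical survival function of censor lengths, stratified by label.

    Censor length is ``death - PD`` for positives and
    ``followup_end - PD`` for negatives.  Returns
    ``{label: [(t, fraction with length > t), ...]}`` with one point per
    distinct observed length, sorted ascending.
    """
    lengths: dict[int, list[int]] = {}
    for inst in instances:
        if inst.label is None:
            continue
        if inst.label == 1:
            length = inst.death_date - inst.prediction_date
        else:
            length = inst.followup_end - inst.prediction_date
        lengths.setdefault(inst.label, []).append(length)
    curves = {}
    for label, vals in lengths.items():
        vals = np.sort(np.asarray(vals))
        n = len(vals)
        ts = np.unique(vals)
        curves[label] = [(int(t), float(np.sum(vals > t) / n)) for t in ts]
    return curves
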