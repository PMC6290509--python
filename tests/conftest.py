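"""Shared fixtures and record factories for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from palliascreen.cohort import CohortInstance, build_cohort, split_cohort
from palliascreen.ehr import CodeCategory, Demographics, EventRecord, PatientRecord
from palliascreen.features import build_vocabulary, vectorize
from palliascreen.model import MLPMortalityClassifier
from palliascreen.simulate import SimConfig, generate_population


def ev(pid: str, day: int, code: str, cat: CodeCategory = CodeCategory.ICD9,
       enc_type=None) -> EventRecord:
    if cat is CodeCategory.ENCOUNTER and enc_type is None:
        enc_type = code
    return EventRecord(pid, day, code, cat, enc_type)


def enc(pid: str, day: int, kind: str = "OUTPATIENT") -> EventRecord:
    return EventRecord(pid, day, kind, CodeCategory.ENCOUNTER, kind)


def make_patient(pid: str = "P1", events=None, birth: int = -10000,
                 gender: str = "FEMALE", race: str = "WHITE",
                 ethnicity: str = "NON-HISPANIC", death=None) -> PatientRecord:
    events = sorted(events or [], key=EventRecord.sort_key)
    return PatientRecord(pid, Demographics(birth, gender, race, ethnicity),
                         events, death)


def encounter_patient(pid: str, enc_days, death=None, extra_events=(),
                      birth: int = -10000) -> PatientRecord:
    """Patient with OUTPATIENT encounters on the given days."""
    events = [enc(pid, d) for d in enc_days] + list(extra_events)
    return make_patient(pid, events, birth=birth, death=death)


def make_instance(pid: str = "P1", pd: int = 2000, events=None, label=0,
                  admitted: bool = False, birth: int = -30000,
                  gender: str = "MALE", death=None,
                  followup_end=None) -> CohortInstance:
    events = sorted(events or [], key=EventRecord.sort_key)
    return CohortInstance(pid, pd, label, admitted, events,
                          Demographics(birth, gender, "WHITE", "NON-HISPANIC"),
                          death, followup_end if followup_end is not None else pd)


@pytest.fixture(scope="session")
def trained_stack():
    """A full study at defaults: 10,000 synthetic patients, cohort, split,
    vocabulary, matrices and a 2x64 SeLU net with snapshot selection.

    Built once per session; several tests (signal recovery, explanation
    recovery, screening enrichment) share it.
    """
    cfg = SimConfig(n_patients=10_000, seed=42)
    population = generate_population(cfg)
    instances = build_cohort(population)
    split = split_cohort(instances, seed=7)
    vocab = build_vocabulary(split.train, min_patient_support=100)
    matrices = {part: vectorize(getattr(split, part), vocab)
                for part in ("train", "validation", "test")}
    model = MLPMortalityClassifier(hidden_layers=2, hidden_width=64,
                                   activation="selu", max_iterations=3000,
                                   seed=3)
    model.fit(matrices["train"].X, matrices["train"].labels,
              matrices["validation"].X, matrices["validation"].labels)
    return {"config": cfg, "population": population, "instances": instances,
            "split": split, "vocab": vocab, "matrices": matrices,
            "model": model}
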