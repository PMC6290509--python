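"""Synthetic EHR generator with a planted proportional-hazards mortality signal.

The generator stands in for a clinical data warehouse: it emits populations
of :class:`~palliascreen.ehr.PatientRecord` whose code assignments and death
times follow a known mechanism, so every downstream stage (cohort
construction, featurization, model fitting, explanation) can be tested for
signal recovery against ground truth.

Mechanism
---------
* Each patient carries each designated *risk code* independently with
  probability ``p_risk_carrier``; the patient's latent log-risk ``r`` is the
  sum of the log-hazard effects of the codes carried.
* Encounters arrive as a homogeneous Poisson process at
  ``encounter_rate_per_year`` over ``calendar_span_days``.  An encounter is
  an inpatient admission with probability ``p_inpatient`` and then emits one
  ENCOUNTER/INPATIENT event per admitted day; otherwise it emits a single
  OUTPATIENT / ER / SCAN encounter event.
* Each encounter also emits coded events (ICD9 / CPT / RXCUI) drawn
  uniformly from the per-category vocabularies; for risk-code carriers each
  draw is replaced, with probability ``p_risk_emission``, by one of the
  carried risk codes (carriers therefore over-express their risk codes).
* Death time is exponential with annual hazard
  ``baseline_annual_death_hazard * exp(r)`` and is recorded iff it falls
  inside the calendar span; events after death are discarded.

Everything is driven by one seeded generator, and the random-call sequence
does not depend on the effect sizes, so raising an effect (same seed) can
only shorten death times — death counts are monotone in the planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .ehr import (
    ENCOUNTER_TYPES,
    CodeCategory,
    Demographics,
    EventRecord,
    PatientRecord,
)

DAYS = 365.0


class SimConfigError(ValueError):
    """Invalid simulation configuration (raised before any sampling)."""


def _default_vocab_sizes() -> dict:
    return {CodeCategory.ICD9: 300, CodeCategory.CPT: 200, CodeCategory.RXCUI: 150}


def _default_risk_codes() -> list:
    # Effects chosen so that carriers are strongly separable: a univariate
    # screen on the pooled risk-code count already ranks deaths well above
    # chance (hazard ratios e^2.4..e^4.0, the territory of metastatic-disease
    # codes against a low background hazard).
    effects = [4.0, 3.6, 3.2, 2.8, 2.4]
    return [(f"ICD9_{i}", CodeCategory.ICD9, e) for i, e in enumerate(effects)]


@dataclass
class SimConfig:
    """Parameters of the synthetic population; defaults define the study
    conditions used throughout the test-suite."""

    n_patients: int = 1000
    seed: int = 0
    calendar_span_days: int = 3650
    encounter_rate_per_year: float = 6.0
    p_inpatient: float = 0.03
    admission_length_mean_days: float = 4.0
    codes_per_encounter_mean: float = 3.0
    vocab_sizes: Mapping[CodeCategory, int] = field(default_factory=_default_vocab_sizes)
    risk_codes: Sequence[tuple] = field(default_factory=_default_risk_codes)
    baseline_annual_death_hazard: float = 0.002
    p_risk_carrier: float = 0.06
    p_risk_emission: float = 0.4

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SimConfigError("n_patients must be non-negative")
        if self.calendar_span_days <= 0:
            raise SimConfigError("calendar_span_days must be positive")
        if self.encounter_rate_per_year <= 0:
            raise SimConfigError("encounter_rate_per_year must be positive")
        for name in ("p_inpatient", "p_risk_carrier", "p_risk_emission"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.baseline_annual_death_hazard < 1.0:
            raise SimConfigError("baseline_annual_death_hazard must be in [0, 1)")
        if self.admission_length_mean_days < 1:
            raise SimConfigError("admission_length_mean_days must be >= 1")
        if self.codes_per_encounter_mean < 1:
            raise SimConfigError("codes_per_encounter_mean must be >= 1")
        for cat in (CodeCategory.ICD9, CodeCategory.CPT, CodeCategory.RXCUI):
            if self.vocab_sizes.get(cat, 0) <= 0:
                raise SimConfigError(f"vocab size for {cat.value} must be positive")
        vocab = {
            (f"{cat.value}_{i}", cat)
            for cat, n in self.vocab_sizes.items()
            for i in range(n)
        }
        for code, cat, effect in self.risk_codes:
            if (code, cat) not in vocab:
                raise SimConfigError(f"risk code {code} not in {cat.value} vocabulary")
            float(effect)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        """Build a config from a plain mapping (e.g. parsed YAML/JSON)."""
        d = dict(d)
        if "vocab_sizes" in d:
            d["vocab_sizes"] = {
                CodeCategory(k): int(v) for k, v in d["vocab_sizes"].items()
            }
        if "risk_codes" in d:
            d["risk_codes"] = [
                (str(c), CodeCategory(cat), float(e)) for c, cat, e in d["risk_codes"]
            ]
        return cls(**d)


def planted_truth(config: SimConfig) -> dict:
    """Ground-truth mapping ``(code, category) -> log_hazard_effect``."""
    config.validate()
    return {(code, cat): float(e) for code, cat, e in config.risk_codes}


def generate_population(config: SimConfig) -> list[PatientRecord]:
    """Sample a population of PatientRecords; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return []

    cats = [CodeCategory.ICD9, CodeCategory.CPT, CodeCategory.RXCUI]
    cat_probs = np.array([0.45, 0.30, 0.25])
    code_names = {
        cat: [f"{cat.value}_{i}" for i in range(config.vocab_sizes[cat])] for cat in cats
    }
    vocab_ns = np.array([config.vocab_sizes[c] for c in cats])
    races = ("WHITE", "BLACK", "ASIAN", "OTHER")
    ethnicities = ("HISPANIC", "NON-HISPANIC")
    risk = list(config.risk_codes)
    effects = np.array([e for _, _, e in risk], dtype=float)
    span = config.calendar_span_days

    # Population-level draws (independent of effect sizes).
    births = rng.integers(-85 * 365, -25 * 365, size=n)
    genders = rng.choice(len(("MALE", "FEMALE", "OTHER")), size=n,
                         p=[0.49, 0.49, 0.02])
    race_ix = rng.integers(0, len(races), size=n)
    eth_ix = rng.integers(0, len(ethnicities), size=n)
    carriers = (
        rng.random((n, len(risk))) < config.p_risk_carrier
        if risk
        else np.zeros((n, 0), dtype=bool)
    )
    n_enc = rng.poisson(config.encounter_rate_per_year * span / DAYS, size=n)

    gender_names = ("MALE", "FEMALE", "OTHER")
    other_enc_types = ("OUTPATIENT", "ER", "SCAN")
    other_enc_probs = np.array([0.75, 0.15, 0.10])

    patients: list[PatientRecord] = []
    death_units = np.empty(n)
    for i in range(n):
        pid = f"P{i:06d}"
        m = int(n_enc[i])
        events: list[EventRecord] = []
        if m > 0:
            starts = np.sort(rng.integers(0, span, size=m))
            inpat = rng.random(m) < config.p_inpatient
            lens = 1 + rng.poisson(config.admission_length_mean_days - 1.0, size=m)
            other_types = rng.choice(len(other_enc_types), size=m, p=other_enc_probs)
            n_codes = 1 + rng.poisson(config.codes_per_encounter_mean - 1.0, size=m)

            for j in range(m):
                s = int(starts[j])
                if inpat[j]:
                    for day in range(s, min(s + int(lens[j]), span)):
                        events.append(
                            EventRecord(pid, day, "INPATIENT",
                                        CodeCategory.ENCOUNTER, "INPATIENT"))
                else:
                    t = other_enc_types[other_types[j]]
                    events.append(EventRecord(pid, s, t, CodeCategory.ENCOUNTER, t))

            total = int(n_codes.sum())
            code_dates = np.repeat(starts, n_codes)
            code_cat_ix = rng.choice(len(cats), size=total, p=cat_probs)
            code_ids = (rng.random(total) * vocab_ns[code_cat_ix]).astype(int)
            carried = np.flatnonzero(carriers[i])
            sub_mask = rng.random(total) < config.p_risk_emission
            sub_pick = rng.integers(0, max(len(carried), 1), size=total)
            for k in range(total):
                d = int(code_dates[k])
                if carried.size and sub_mask[k]:
                    code, cat, _ = risk[carried[sub_pick[k]]]
                    events.append(EventRecord(pid, d, code, cat))
                else:
                    cat = cats[code_cat_ix[k]]
                    events.append(EventRecord(pid, d, code_names[cat][code_ids[k]], cat))

        death_units[i] = rng.exponential(1.0)
        demo = Demographics(int(births[i]), gender_names[genders[i]],
                            races[race_ix[i]], ethnicities[eth_ix[i]])
        events.sort(key=EventRecord.sort_key)
        patients.append(PatientRecord(pid, demo, events, None))

    # Death times scaled by each patient's hazard after the shared random
    # stream is consumed, so effects never perturb the draw sequence.
    log_r = carriers @ effects if risk else np.zeros(n)
    if config.baseline_annual_death_hazard > 0:
        annual_hazard = config.baseline_annual_death_hazard * np.exp(log_r)
        death_days = death_units * DAYS / annual_hazard
        for i, p in enumerate(patients):
            if death_days[i] < span:
                p.death_date = int(death_days[i])
                p.events = [ev for ev in p.events if ev.date <= p.death_date]
    return patients
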