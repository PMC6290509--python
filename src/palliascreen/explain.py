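"""Counterfactual code-ablation explanations for individual predictions.

For each distinct code observed in a patient's window, the explanation
answers: *all else equal, how would the predicted death probability change
if this patient had never received this code?*  All occurrences of the code
are removed from the (censored) event list, every feature — slice counts
and the per-category summary statistics — is recomputed, and the influence
is the drop in natural-log probability::

    influence = log p(original) - log p(ablated)

Demographics are perturbed rather than ablated: age is zeroed, gender is
swapped to the opposite sex.  Only factors with positive influence (those
whose removal lowers the predicted probability) are reported, ranked
descending, top 5 per display category (Diagnostic, Procedural,
Medication, Encounter, Demographic).

Codes absent from the window are never scored: their ablation is the
identity, so their influence is exactly zero by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import CohortInstance
from .ehr import CodeCategory
from .features import (
    WINDOW_DAYS,
    FeatureName,
    FeatureVocabulary,
    STAT_KINDS,
    vectorize,
)
from .model import MLPMortalityClassifier, predict_probability

P_CLIP = 1e-12

CATEGORY_DISPLAY = {
    CodeCategory.ICD9: "Diagnostic",
    CodeCategory.CPT: "Procedural",
    CodeCategory.RXCUI: "Medication",
    CodeCategory.ENCOUNTER: "Encounter",
}
DEMOGRAPHIC_DISPLAY = "Demographic"
DISPLAY_ORDER = ("Diagnostic", "Procedural", "Medication", "Encounter", "Demographic")


@dataclass(frozen=True)
class InfluenceEntry:
    code: str
    category: str        # display category
    value: float         # observed feature value (window count, age, ...)
    influence: float     # log p_original - log p_ablated
    description: str


@dataclass
class ExplanationReport:
    patient_id: str
    probability_score: float
    factors: dict  # display category -> list[InfluenceEntry], sorted desc

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "probability_score": self.probability_score,
            "factors": {cat: [dataclasses.asdict(e) for e in entries]
                        for cat, entries in self.factors.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        """Aligned factor table (Factors / Code / Value / Influence / Description)."""
        lines = [f"Patient {self.patient_id}",
                 f"Probability score {self.probability_score:.3f}", ""]
        header = f"{'Code':<24}{'Value':>8}  {'Influence':>10}  Description"
        for cat in DISPLAY_ORDER:
            entries = self.factors.get(cat, [])
            lines.append(f"Top {cat} factors")
            if entries:
                lines.append(header)
            for e in entries:
                value = f"{e.value:g}"
                lines.append(f"{e.code:<24}{value:>8}  {e.influence:>10.4f}  "
                             f"{e.description}")
            lines.append("")
        lines.append("Only factors that contributed to a drop in probability "
                     "score are reported")
        return "\n".join(lines)


def _log_clipped(p: float) -> float:
    return math.log(min(max(p, P_CLIP), 1.0 - P_CLIP))


def _probability(model, vocabulary, instance) -> float:
    fm = vectorize([instance], vocabulary)
    return float(predict_probability(model, fm.X)[0])


def ablate_code(instance: CohortInstance, code: str,
                category: CodeCategory) -> CohortInstance:
    """Copy of ``instance`` with every event matching (code, category) removed.

    The input is never mutated; all features downstream are recomputed from
    the reduced event list."""
    events = [ev for ev in instance.events
              if not (ev.code == code and ev.category is category)]
    return replace(instance, events=events)


def code_influence(model: MLPMortalityClassifier, vocabulary: FeatureVocabulary,
                   instance: CohortInstance, code: str,
                   category: CodeCategory) -> float:
    """Drop in log-probability when all occurrences of a code are removed."""
    ablated = ablate_code(instance, code, category)
    if len(ablated.events) == len(instance.events):
        return 0.0
    p0 = _probability(model, vocabulary, instance)
    p1 = _probability(model, vocabulary, ablated)
    return _log_clipped(p0) - _log_clipped(p1)


def _window_codes(instance: CohortInstance) -> dict:
    """Distinct (code, category) in the observation window with their counts."""
    counts: dict = {}
    pd_ = instance.prediction_date
    for ev in instance.events:
        if 0 <= pd_ - ev.date < WINDOW_DAYS:
            key = (ev.code, ev.category)
            counts[key] = counts.get(key, 0) + 1
    return counts


def demographic_influences(model: MLPMortalityClassifier,
                           vocabulary: FeatureVocabulary,
                           instance: CohortInstance) -> list[InfluenceEntry]:
    """Age-zeroing and gender-swap counterfactuals (race/ethnicity untouched)."""
    fm = vectorize([instance], vocabulary)
    x0 = fm.X.toarray()[0]
    p0 = float(predict_probability(model, x0[None, :])[0])
    entries = []

    age_ix = vocabulary.index.get(str(FeatureName.demo("age")))
    age = instance.demographics.age_at(instance.prediction_date)
    if age_ix is not None and x0[age_ix] != 0.0:
        x = x0.copy()
        x[age_ix] = 0.0
        p1 = float(predict_probability(model, x[None, :])[0])
        entries.append(InfluenceEntry(
            "Age", DEMOGRAPHIC_DISPLAY, float(age),
            _log_clipped(p0) - _log_clipped(p1),
            "Age of patient in years at prediction time"))

    gender = instance.demographics.gender
    opposite = {"MALE": "FEMALE", "FEMALE": "MALE"}.get(gender)
    if opposite is not None:
        cur_ix = vocabulary.index.get(str(FeatureName.demo("gender", gender)))
        opp_ix = vocabulary.index.get(str(FeatureName.demo("gender", opposite)))
        if cur_ix is not None or opp_ix is not None:
            x = x0.copy()
            if cur_ix is not None:
                x[cur_ix] = 0.0
            if opp_ix is not None:
                x[opp_ix] = 1.0
            p1 = float(predict_probability(model, x[None, :])[0])
            entries.append(InfluenceEntry(
                "Gender", DEMOGRAPHIC_DISPLAY, 1.0,
                _log_clipped(p0) - _log_clipped(p1),
                f"Gender swapped from {gender} to {opposite}"))
    return entries


_STAT_DESCRIPTIONS = {
    "unique_count": "Number of unique codes in the category",
    "total_count": "Count of all codes in the category",
    "max_per_day": "Maximum number of codes in any day",
    "min_nonzero_per_day": "Minimum (non-zero) number of codes in any day",
    "range_per_day": "Range of codes across days",
    "mean_per_day": "Mean number of codes per day",
    "var_per_day": "Variance in number of codes assigned per day",
}


def _stat_influences(model, vocabulary, instance, x0, p0) -> list[InfluenceEntry]:
    entries = []
    for name in vocabulary.names:
        if name.kind != "STAT":
            continue
        j = vocabulary.index[str(name)]
        if x0[j] == 0.0:
            continue
        x = x0.copy()
        x[j] = 0.0
        p1 = float(predict_probability(model, x[None, :])[0])
        entries.append(InfluenceEntry(
            name.parts[1], CATEGORY_DISPLAY[name.category], float(x0[j]),
            _log_clipped(p0) - _log_clipped(p1),
            f"Summary statistic ({_STAT_DESCRIPTIONS[name.parts[1]]})"))
    return entries


def explain(model: MLPMortalityClassifier, vocabulary: FeatureVocabulary,
            instance: CohortInstance, top_k: int = 5,
            include_stats: bool = False,
            descriptions: Optional[Mapping] = None) -> ExplanationReport:
    """Build the full per-patient explanation report.

    Every distinct (code, category) present in the window is ablated; with
    ``include_stats=True`` each non-zero summary-statistic feature is
    additionally zeroed as a standalone factor.  Entries with non-positive
    influence are discarded; within each category entries sort by
    descending influence, ties broken lexicographically by code; lists are
    truncated to ``top_k``.
    """
    descriptions = descriptions or {}
    p0 = _probability(model, vocabulary, instance)
    window = _window_codes(instance)

    entries: list[InfluenceEntry] = []
    for (code, category), count in window.items():
        infl = code_influence(model, vocabulary, instance, code, category)
        desc = descriptions.get(code, f"{category.value} code {code}")
        entries.append(InfluenceEntry(code, CATEGORY_DISPLAY[category],
                                      float(count), infl, desc))
    if include_stats:
        fm = vectorize([instance], vocabulary)
        x0 = fm.X.toarray()[0]
        entries.extend(_stat_influences(model, vocabulary, instance, x0, p0))
    entries.extend(demographic_influences(model, vocabulary, instance))

    factors: dict = {cat: [] for cat in DISPLAY_ORDER}
    for e in entries:
        if e.influence > 0.0:
            factors[e.category].append(e)
    for cat in factors:
        factors[cat].sort(key=lambda e: (-e.influence, e.code))
        factors[cat] = factors[cat][:top_k]
    return ExplanationReport(instance.patient_id, p0, factors)
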