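"""Featurization of censored patient histories into named sparse vectors.

Each instance is observed over the 12 months up to its prediction date
(PD).  The window is partitioned into four recency-weighted *slices*::

    slice 1: (PD-30,  PD]        30 days  (most recent)
    slice 2: (PD-90,  PD-30]     60 days
    slice 3: (PD-180, PD-90]     90 days
    slice 4: (PD-365, PD-180]   185 days  (oldest)

Intervals are half-open ``(start, end]`` so the PD's own events are
included and every event in the window lands in exactly one slice.

Three families of features are emitted, each with a structured, losslessly
serializable name:

* ``SLICE|category|code|k`` — occurrences of a code within slice k;
* ``STAT|category|kind`` — per-category summary statistics over the whole
  window (unique/total code counts and max / min / range / mean / variance
  of the daily code tally over *active* days, i.e. days with at least one
  event of the category);
* ``DEMO|field[|level]`` — age in years at PD (numeric) and one-hot
  gender / race / ethnicity with levels fixed by the training data.

The vocabulary is built on training instances only; SLICE/STAT features
supported by 100 or fewer training patients are pruned (threshold
configurable), demographics are always retained.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortInstance
from .ehr import CodeCategory

WINDOW_DAYS = 365
#: slice index -> (start_offset, end_offset]; event with age a = PD - date
#: falls in slice k iff start_offset <= a-0 ... handled via _slice_of.
SLICE_BOUNDS = {1: (0, 30), 2: (30, 90), 3: (90, 180), 4: (180, 365)}
SLICE_DURATIONS = {1: 30, 2: 60, 3: 90, 4: 185}

STAT_KINDS = ("unique_count", "total_count", "max_per_day", "min_nonzero_per_day",
              "range_per_day", "mean_per_day", "var_per_day")

_SEP = "|"


@dataclass(frozen=True)
class ObservationSlices:
    """Absolute ``(start, end]`` intervals of the window and its slices."""

    window: tuple
    slices: dict

    @property
    def durations(self) -> dict:
        return {k: e - s for k, (s, e) in self.slices.items()}


def slice_intervals(prediction_date: int) -> ObservationSlices:
    pd_ = prediction_date
    return ObservationSlices(
        window=(pd_ - WINDOW_DAYS, pd_),
        slices={k: (pd_ - hi, pd_ - lo) for k, (lo, hi) in SLICE_BOUNDS.items()},
    )


def _slice_of(prediction_date: int, date: int) -> Optional[int]:
    age = prediction_date - date
    if age < 0 or age >= WINDOW_DAYS:
        return None
    for k, (lo, hi) in SLICE_BOUNDS.items():
        if lo <= age < hi:
            return k
    return None  # pragma: no cover


@dataclass(frozen=True, order=True)
class FeatureName:
    """Structured feature identifier; serializes losslessly via str()."""

    kind: str  # SLICE | STAT | DEMO
    parts: tuple

    def __str__(self) -> str:
        return _SEP.join((self.kind,) + tuple(str(p) for p in self.parts))

    @classmethod
    def slice(cls, category: CodeCategory, code: str, slice_index: int) -> "FeatureName":
        return cls("SLICE", (category.value, code, slice_index))

    @classmethod
    def stat(cls, category: CodeCategory, stat_kind: str) -> "FeatureName":
        return cls("STAT", (category.value, stat_kind))

    @classmethod
    def demo(cls, fieldname: str, level: Optional[str] = None) -> "FeatureName":
        return cls("DEMO", (fieldname,) if level is None else (fieldname, level))

    @classmethod
    def from_string(cls, s: str) -> "FeatureName":
        parts = s.split(_SEP)
        kind = parts[0]
        if kind == "SLICE":
            cat, code, k = parts[1], _SEP.join(parts[2:-1]), int(parts[-1])
            return cls.slice(CodeCategory(cat), code, k)
        if kind == "STAT":
            return cls.stat(CodeCategory(parts[1]), parts[2])
        if kind == "DEMO":
            return cls("DEMO", tuple(parts[1:]))
        raise ValueError(f"unknown feature kind in {s!r}")

    @property
    def category(self) -> Optional[CodeCategory]:
        if self.kind in ("SLICE", "STAT"):
            return CodeCategory(self.parts[0])
        return None


def slice_code_counts(instance: CohortInstance) -> dict:
    """``FeatureName.slice -> count`` over the instance's window; zero counts
    are never materialized."""
    pd_ = instance.prediction_date
    counts: Counter = Counter()
    for ev in instance.events:
        k = _slice_of(pd_, ev.date)
        if k is not None:
            counts[FeatureName.slice(ev.category, ev.code, k)] += 1
    return dict(counts)


def category_summary_stats(instance: CohortInstance,
                           category: CodeCategory) -> dict:
    """Window-level summary statistics for one code category.

    Daily statistics are computed over active days only (days with >= 1
    event of the category); variance is the population variance.  An empty
    category emits no features at all.
    """
    pd_ = instance.prediction_date
    daily: Counter = Counter()
    codes = set()
    total = 0
    for ev in instance.events:
        if ev.category is category and 0 <= pd_ - ev.date < WINDOW_DAYS:
            daily[ev.date] += 1
            codes.add(ev.code)
            total += 1
    if not total:
        return {}
    tallies = np.array(list(daily.values()), dtype=float)
    stat = FeatureName.stat
    return {
        stat(category, "unique_count"): float(len(codes)),
        stat(category, "total_count"): float(total),
        stat(category, "max_per_day"): float(tallies.max()),
        stat(category, "min_nonzero_per_day"): float(tallies.min()),
        stat(category, "range_per_day"): float(tallies.max() - tallies.min()),
        stat(category, "mean_per_day"): float(tallies.mean()),
        stat(category, "var_per_day"): float(tallies.var()),
    }


def demographic_features(instance: CohortInstance) -> dict:
    """Age at PD (numeric) plus one-hot gender/race/ethnicity indicators."""
    d = instance.demographics
    out = {FeatureName.demo("age"): float(d.age_at(instance.prediction_date))}
    for fieldname, value in (("gender", d.gender), ("race", d.race),
                             ("ethnicity", d.ethnicity)):
        out[FeatureName.demo(fieldname, value)] = 1.0
    return out


def instance_features(instance: CohortInstance) -> dict:
    """All features of one instance: slice counts, summary stats, demographics."""
    feats = slice_code_counts(instance)
    for cat in CodeCategory:
        feats.update(category_summary_stats(instance, cat))
    feats.update(demographic_features(instance))
    return feats


@dataclass
class FeatureVocabulary:
    """Ordered feature names with training-set patient support counts."""

    names: list
    support: dict

    def __post_init__(self):
        self.index = {str(n): i for i, n in enumerate(self.names)}

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name) -> bool:
        return str(name) in self.index

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# palliascreen vocabulary v1\n")
            for n in self.names:
                fh.write(f"{n}\t{self.support.get(str(n), 0)}\n")

    @classmethod
    def load(cls, path) -> "FeatureVocabulary":
        names, support = [], {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                s, sup = line.rsplit("\t", 1)
                names.append(FeatureName.from_string(s))
                support[s] = int(sup)
        return cls(names, support)


@dataclass
class FeatureMatrix:
    """Sparse design matrix with aligned labels and row ids.

    ``labels`` uses -1 for unlabeled (screening) rows.
    """

    X: sp.csr_matrix
    labels: np.ndarray
    row_ids: list

    def save(self, mtx_path, sidecar_path) -> None:
        scipy.io.mmwrite(str(mtx_path), self.X)
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            fh.write("# row_id\tlabel\n")
            for rid, lab in zip(self.row_ids, self.labels):
                fh.write(f"{rid}\t{int(lab)}\n")

    @classmethod
    def load(cls, mtx_path, sidecar_path) -> "FeatureMatrix":
        X = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
        row_ids, labels = [], []
        with open(sidecar_path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                rid, lab = line.split("\t")
                row_ids.append(rid)
                labels.append(int(lab))
        return cls(X, np.asarray(labels), row_ids)


class ClinicalFeaturizer(TransformerMixin, BaseEstimator):
    """Vocabulary-building vectorizer over cohort instances.

    ``fit`` scans training instances, counts per-feature patient support and
    prunes SLICE/STAT features occurring in ``min_patient_support`` or fewer
    patients (demographics always kept); ``transform`` maps instances onto
    the learned vocabulary as a CSR matrix.  Ordering is lexicographic by
    serialized feature name, hence deterministic.
    """

    def __init__(self, min_patient_support: int = 100):
        self.min_patient_support = min_patient_support

    def fit(self, X: Sequence[CohortInstance], y=None) -> "ClinicalFeaturizer":
        instances = list(X)
        if not instances:
            raise ValueError("cannot build a vocabulary from an empty training set")
        support: Counter = Counter()
        for inst in instances:
            for name, value in instance_features(inst).items():
                if value != 0.0:
                    support[name] += 1
        kept = [n for n in support
                if n.kind == "DEMO" or support[n] > self.min_patient_support]
        kept.sort(key=str)
        self.vocabulary_ = FeatureVocabulary(kept, {str(n): support[n] for n in kept})
        self.n_features_in_ = len(kept)
        return self

    def transform(self, X: Sequence[CohortInstance]) -> sp.csr_matrix:
        if not hasattr(self, "vocabulary_"):
            raise RuntimeError("ClinicalFeaturizer is not fitted")
        return vectorize(X, self.vocabulary_).X

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([str(n) for n in self.vocabulary_.names], dtype=object)


def build_vocabulary(training_instances: Sequence[CohortInstance],
                     min_patient_support: int = 100) -> FeatureVocabulary:
    """Functional wrapper over :class:`ClinicalFeaturizer.fit`."""
    return ClinicalFeaturizer(min_patient_support).fit(training_instances).vocabulary_


def vectorize(instances: Iterable[CohortInstance],
              vocabulary: FeatureVocabulary) -> FeatureMatrix:
    """Map instances onto a fixed vocabulary; unknown features are dropped,
    known-but-absent features are zero."""
    rows, cols, vals = [], [], []
    labels, row_ids = [], []
    idx = vocabulary.index
    for r, inst in enumerate(instances):
        row_ids.append(inst.patient_id)
        labels.append(-1 if inst.label is None else int(inst.label))
        for name, value in instance_features(inst).items():
            j = idx.get(str(name))
            if j is not None and value != 0.0:
                rows.append(r)
                cols.append(j)
                vals.append(value)
    X = sp.csr_matrix((vals, (rows, cols)),
                      shape=(len(row_ids), len(vocabulary)), dtype=np.float64)
    return FeatureMatrix(X, np.asarray(labels), row_ids)
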