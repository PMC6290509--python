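"""Slice intervals, counts, summary statistics, vocabulary and matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palliascreen.cohort import CohortInstance
from palliascreen.ehr import CodeCategory
from palliascreen.features import (
    ClinicalFeaturizer,
    FeatureMatrix,
    FeatureName,
    FeatureVocabulary,
    build_vocabulary,
    category_summary_stats,
    demographic_features,
    instance_features,
    slice_code_counts,
    slice_intervals,
    vectorize,
)

from conftest import ev, make_instance

ICD9 = CodeCategory.ICD9
CPT = CodeCategory.CPT


class TestSliceGeometry:
    def test_intervals_at_pd_2000(self):
        s = slice_intervals(2000)
        assert s.window == (1635, 2000)
        assert s.slices == {1: (1970, 2000), 2: (1910, 1970),
                            3: (1820, 1910), 4: (1635, 1820)}

    def test_durations_sum_to_window(self):
        s = slice_intervals(0)
        assert s.durations == {1: 30, 2: 60, 3: 90, 4: 185}
        assert sum(s.durations.values()) == 365

    def test_boundary_event_in_older_slice(self):
        # an event exactly at PD-30 belongs to slice 2 under (start, end]
        inst = make_instance(pd=2000, events=[ev("P1", 1970, "x")])
        counts = slice_code_counts(inst)
        assert counts == {FeatureName.slice(ICD9, "x", 2): 1}

    def test_pd_day_event_in_slice_1(self):
        inst = make_instance(pd=2000, events=[ev("P1", 2000, "x")])
        assert counts_of(inst) == {("x", 1): 1}


def counts_of(inst):
    return {(n.parts[1], n.parts[2]): v
            for n, v in slice_code_counts(inst).items()}


class TestSliceCounts:
    def test_empty_window(self):
        assert slice_code_counts(make_instance(events=[])) == {}

    def test_worked_example(self):
        pd = 2000
        inst = make_instance(pd=pd, events=[
            ev("P1", pd - 5, "410.1"), ev("P1", pd - 10, "410.1"),
            ev("P1", pd - 40, "410.1")])
        assert counts_of(inst) == {("410.1", 1): 2, ("410.1", 2): 1}

    def test_event_outside_window_ignored(self):
        inst = make_instance(pd=2000, events=[ev("P1", 1600, "x")])
        assert slice_code_counts(inst) == {}


class TestSummaryStats:
    def stats(self, inst, cat=ICD9):
        return {n.parts[1]: v for n, v in category_summary_stats(inst, cat).items()}

    def test_two_active_days(self):
        pd = 2000
        inst = make_instance(pd=pd, events=[
            ev("P1", pd - 3, "a"), ev("P1", pd - 3, "b"), ev("P1", pd - 3, "a"),
            ev("P1", pd - 9, "c")])
        s = self.stats(inst)
        assert s == {"unique_count": 3, "total_count": 4, "max_per_day": 3,
                     "min_nonzero_per_day": 1, "range_per_day": 2,
                     "mean_per_day": 2, "var_per_day": 1}

    def test_single_active_day(self):
        pd = 2000
        inst = make_instance(pd=pd, events=[ev("P1", pd - 1, c)
                                            for c in ("a", "a", "b", "b")])
        s = self.stats(inst)
        assert s["unique_count"] == 2 and s["total_count"] == 4
        assert s["max_per_day"] == s["min_nonzero_per_day"] == 4
        assert s["range_per_day"] == 0 and s["var_per_day"] == 0

    def test_empty_category_emits_nothing(self):
        inst = make_instance(events=[ev("P1", 1990, "x", ICD9)])
        assert category_summary_stats(inst, CPT) == {}


class TestDemographics:
    def test_age_81(self):
        inst = make_instance(pd=0, birth=-29586)
        feats = demographic_features(inst)
        assert feats[FeatureName.demo("age")] == 81

    def test_age_zero_on_birth_day(self):
        inst = make_instance(pd=100, birth=100)
        assert demographic_features(inst)[FeatureName.demo("age")] == 0

    def test_gender_one_hot(self):
        feats = demographic_features(make_instance(gender="MALE"))
        assert feats[FeatureName.demo("gender", "MALE")] == 1.0
        assert FeatureName.demo("gender", "FEMALE") not in feats


def one_code_instance(pid, code="X", n_events=1, pd=2000):
    return make_instance(pid, pd=pd,
                         events=[ev(pid, pd - 1 - i, code) for i in range(n_events)])


class TestVocabulary:
    def test_pruning_boundary(self):
        # support == threshold pruned, support == threshold+1 kept
        for n, kept in ((100, False), (101, True)):
            insts = [one_code_instance(f"P{i}") for i in range(n)]
            insts += [make_instance(f"Q{i}", events=[]) for i in range(5)]
            vocab = build_vocabulary(insts, min_patient_support=100)
            assert (FeatureName.slice(ICD9, "X", 1) in vocab) is kept

    def test_demographics_always_retained(self):
        vocab = build_vocabulary([make_instance("P1", events=[])], 100)
        assert FeatureName.demo("age") in vocab

    def test_deterministic(self):
        insts = [one_code_instance(f"P{i}", code=f"C{i % 3}") for i in range(30)]
        a = build_vocabulary(insts, 5)
        b = build_vocabulary(insts, 5)
        assert [str(n) for n in a.names] == [str(n) for n in b.names]

    def test_supported_code_present(self):
        insts = [one_code_instance(f"P{i}", code="X" if i < 150 else f"Y{i}")
                 for i in range(1000)]
        vocab = build_vocabulary(insts, 100)
        assert FeatureName.slice(ICD9, "X", 1) in vocab
        assert FeatureName.stat(ICD9, "total_count") in vocab

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            build_vocabulary([], 100)

    def test_pruning_monotone(self):
        insts = [one_code_instance(f"P{i}", code=f"C{i % 4}") for i in range(40)]
        sizes = [len(build_vocabulary(insts, t)) for t in (0, 3, 9, 100)]
        assert sizes == sorted(sizes, reverse=True)

    def test_round_trip_file(self, tmp_path):
        insts = [one_code_instance(f"P{i}") for i in range(10)]
        vocab = build_vocabulary(insts, 2)
        vocab.save(tmp_path / "v.txt")
        loaded = FeatureVocabulary.load(tmp_path / "v.txt")
        assert [str(n) for n in loaded.names] == [str(n) for n in vocab.names]
        assert loaded.support == vocab.support


class TestVectorize:
    def test_out_of_vocabulary_row_is_zero(self):
        # vocabulary knows only ICD9 features; a CPT-only instance can hit
        # nothing but demographics
        vocab = build_vocabulary([one_code_instance("P0")], 0)
        cpt_inst = make_instance("P1", pd=2000,
                                 events=[ev("P1", 1999, "OTHER", CPT)])
        fm = vectorize([cpt_inst], vocab)
        demo_cols = {i for i, n in enumerate(vocab.names) if n.kind == "DEMO"}
        assert set(fm.X.nonzero()[1]).issubset(demo_cols)

    def test_column_count_matches_vocabulary(self):
        insts = [one_code_instance(f"P{i}") for i in range(5)]
        vocab = build_vocabulary(insts, 0)
        assert vectorize(insts[:2], vocab).X.shape == (2, len(vocab))

    def test_row_permutation_permutes_matrix(self):
        insts = [one_code_instance(f"P{i}", code=f"C{i}") for i in range(6)]
        vocab = build_vocabulary(insts, 0)
        a = vectorize(insts, vocab)
        b = vectorize(insts[::-1], vocab)
        assert (a.X.toarray() == b.X.toarray()[::-1]).all()
        assert a.row_ids == b.row_ids[::-1]

    def test_matrix_round_trip(self, tmp_path):
        insts = [one_code_instance(f"P{i}", n_events=i + 1) for i in range(4)]
        vocab = build_vocabulary(insts, 0)
        fm = vectorize(insts, vocab)
        fm.save(tmp_path / "m.mtx", tmp_path / "rows.tsv")
        loaded = FeatureMatrix.load(tmp_path / "m.mtx", tmp_path / "rows.tsv")
        assert (loaded.X.toarray() == fm.X.toarray()).all()
        assert loaded.row_ids == fm.row_ids
        assert (loaded.labels == fm.labels).all()

    def test_sklearn_transformer_interface(self):
        insts = [one_code_instance(f"P{i}") for i in range(8)]
        fz = ClinicalFeaturizer(min_patient_support=0).fit(insts)
        X = fz.transform(insts)
        assert X.shape == (8, fz.n_features_in_)
        assert fz.get_params() == {"min_patient_support": 0}
        assert len(fz.get_feature_names_out()) == X.shape[1]


# ------------------------------------------------------ conservation property

@st.composite
def random_instances(draw):
    pd = draw(st.integers(400, 3000))
    events = []
    for _ in range(draw(st.integers(0, 25))):
        cat = draw(st.sampled_from([ICD9, CPT, CodeCategory.RXCUI]))
        code = f"{cat.value}_{draw(st.integers(0, 5))}"
        day = pd - draw(st.integers(0, 420))
        events.append(ev("H", max(day, 0), code, cat))
    return make_instance("H", pd=pd, events=events)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(random_instances())
def test_slice_counts_conserve_window_totals(inst):
    """Per-code slice counts sum to window counts; per-category code sums
    equal the STAT total_count."""
    pd = inst.prediction_date
    window = [e for e in inst.events if 0 <= pd - e.date < 365]
    counts = slice_code_counts(inst)
    for cat in (ICD9, CPT, CodeCategory.RXCUI):
        codes = {e.code for e in window if e.category is cat}
        for code in codes:
            total = sum(1 for e in window if e.code == code and e.category is cat)
            assert sum(v for n, v in counts.items()
                       if n.parts[0] == cat.value and n.parts[1] == code) == total
        stats = category_summary_stats(inst, cat)
        cat_total = sum(1 for e in window if e.category is cat)
        if cat_total:
            assert stats[FeatureName.stat(cat, "total_count")] == cat_total
        feats = instance_features(inst)
        for n, v in feats.items():
            assert np.isfinite(v)
            if n.kind != "DEMO" or n.parts[0] != "age":
                assert v >= 0


def test_feature_name_serialization_round_trip():
    names = [FeatureName.slice(ICD9, "410.1", 3),
             FeatureName.stat(CPT, "var_per_day"),
             FeatureName.demo("age"), FeatureName.demo("gender", "MALE")]
    for n in names:
        assert FeatureName.from_string(str(n)) == n
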