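"""Counterfactual ablation: zero-influence law, closed forms, reports."""

import copy
import math

import numpy as np
import pytest

from palliascreen.ehr import CodeCategory
from palliascreen.explain import (
    ablate_code,
    code_influence,
    demographic_influences,
    explain,
)
from palliascreen.features import FeatureName, FeatureVocabulary, vectorize
from palliascreen.model import MLPMortalityClassifier, predict_probability

from conftest import ev, make_instance

ICD9 = CodeCategory.ICD9
CPT = CodeCategory.CPT


def linear_model(vocab, weights, bias=0.0):
    """Logistic model with hand-set weights keyed by feature name."""
    m = MLPMortalityClassifier(hidden_layers=0)
    w = np.zeros((len(vocab), 1))
    for name, value in weights.items():
        w[vocab.index[str(name)], 0] = value
    m.coefs_ = [w]
    m.intercepts_ = [np.array([bias])]
    m.n_features_in_ = len(vocab)
    m.classes_ = np.array([0, 1])
    return m


def vocab_of(names):
    return FeatureVocabulary(sorted(names, key=str), {str(n): 999 for n in names})


def sigma(z):
    return 1.0 / (1.0 + math.exp(-z))


class TestAblation:
    def test_absent_code_is_identity(self):
        inst = make_instance(events=[ev("P1", 1990, "a")])
        assert ablate_code(inst, "zz", ICD9).events == inst.events

    def test_only_code_leaves_empty_instance(self):
        inst = make_instance(events=[ev("P1", 1990, "a"), ev("P1", 1991, "a")])
        out = ablate_code(inst, "a", ICD9)
        assert out.events == []

    def test_stats_recomputed_after_ablation(self):
        pd = 2000
        events = [ev("P1", pd - 1 - i, "250.0") for i in range(3)]
        events += [ev("P1", pd - 1 - i, f"c{i}") for i in range(7)]
        inst = make_instance(pd=pd, events=events)
        from palliascreen.features import category_summary_stats
        before = category_summary_stats(inst, ICD9)
        after = category_summary_stats(ablate_code(inst, "250.0", ICD9), ICD9)
        tc, uc = FeatureName.stat(ICD9, "total_count"), FeatureName.stat(ICD9, "unique_count")
        assert before[tc] - after[tc] == 3
        assert before[uc] - after[uc] == 1

    def test_input_never_mutated(self):
        inst = make_instance(events=[ev("P1", 1990, "a"), ev("P1", 1991, "b")])
        snapshot = copy.deepcopy(inst)
        ablate_code(inst, "a", ICD9)
        assert inst == snapshot


class TestCodeInfluence:
    def test_zero_influence_for_absent_codes(self):
        inst = make_instance(events=[ev("P1", 1990, "a")])
        names = [FeatureName.slice(ICD9, "a", 1), FeatureName.demo("age")]
        vocab = vocab_of(names)
        model = linear_model(vocab, {names[0]: 1.0})
        for code in ("b", "zz", "410.1"):
            assert code_influence(model, vocab, inst, code, ICD9) == 0.0

    def test_zero_weight_model_gives_zero_influence(self):
        inst = make_instance(events=[ev("P1", 1990, "a")])
        vocab = vocab_of([FeatureName.slice(ICD9, "a", 1)])
        model = linear_model(vocab, {})
        assert code_influence(model, vocab, inst, "a", ICD9) == 0.0

    def test_closed_form_single_feature_logistic(self):
        """influence = log sigma(w*c + b) - log sigma(b) for a count-c code."""
        c, w, b = 3, 0.7, -1.1
        pd = 2000
        inst = make_instance(pd=pd, events=[ev("P1", pd - 2 - i, "x")
                                            for i in range(c)])
        name = FeatureName.slice(ICD9, "x", 1)
        vocab = vocab_of([name])
        model = linear_model(vocab, {name: w}, bias=b)
        expected = math.log(sigma(w * c + b)) - math.log(sigma(b))
        assert code_influence(model, vocab, inst, "x", ICD9) == pytest.approx(
            expected, abs=1e-9)

    def test_closed_form_with_background_logit(self):
        pd = 2000
        inst = make_instance(pd=pd, events=[ev("P1", pd - 1, "x"),
                                            ev("P1", pd - 3, "y", CPT)])
        nx = FeatureName.slice(ICD9, "x", 1)
        ny = FeatureName.slice(CPT, "y", 1)
        vocab = vocab_of([nx, ny])
        w, v, b = 0.9, -0.4, 0.2
        model = linear_model(vocab, {nx: w, ny: v}, bias=b)
        rest = v * 1 + b
        expected = math.log(sigma(w + rest)) - math.log(sigma(rest))
        assert code_influence(model, vocab, inst, "x", ICD9) == pytest.approx(
            expected, abs=1e-9)


class TestDemographicInfluences:
    def make_vocab(self):
        return vocab_of([FeatureName.demo("age"),
                         FeatureName.demo("gender", "MALE"),
                         FeatureName.demo("gender", "FEMALE")])

    def test_model_ignoring_demographics(self):
        vocab = self.make_vocab()
        model = linear_model(vocab, {})
        inst = make_instance(birth=-30000, gender="MALE")
        for entry in demographic_influences(model, vocab, inst):
            assert entry.influence == 0.0

    def test_age_closed_form(self):
        vocab = self.make_vocab()
        w = 0.03
        model = linear_model(vocab, {FeatureName.demo("age"): w})
        inst = make_instance(pd=2000, birth=2000 - 29586, gender="OTHER")
        age = 81
        (entry,) = demographic_influences(model, vocab, inst)
        expected = math.log(sigma(w * age)) - math.log(sigma(0.0))
        assert entry.influence == pytest.approx(expected, abs=1e-9)

    def test_age_zero_patient_has_no_age_entry(self):
        vocab = self.make_vocab()
        model = linear_model(vocab, {FeatureName.demo("age"): 1.0})
        inst = make_instance(pd=100, birth=100, gender="OTHER")
        assert demographic_influences(model, vocab, inst) == []

    def test_gender_swap_direction(self):
        vocab = self.make_vocab()
        model = linear_model(vocab, {FeatureName.demo("gender", "MALE"): 0.5})
        inst = make_instance(gender="MALE")
        entries = {e.code: e for e in demographic_influences(model, vocab, inst)}
        expected = math.log(sigma(0.5)) - math.log(sigma(0.0))
        assert entries["Gender"].influence == pytest.approx(expected, abs=1e-9)


class TestExplainReport:
    def setup_model(self):
        pd = 2000
        events = ([ev("P1", pd - 2, "icd_a")] * 0
                  + [ev("P1", pd - 2 - i, "icd_a") for i in range(4)]
                  + [ev("P1", pd - 5, "icd_b")]
                  + [ev("P1", pd - 3, "cpt_a", CPT)])
        inst = make_instance(pd=pd, events=events)
        names = [FeatureName.slice(ICD9, "icd_a", 1),
                 FeatureName.slice(ICD9, "icd_b", 1),
                 FeatureName.slice(CPT, "cpt_a", 1),
                 FeatureName.demo("age")]
        vocab = vocab_of(names)
        model = linear_model(vocab, {names[0]: 0.8, names[1]: 0.2,
                                     names[2]: -0.5})
        return model, vocab, inst

    def test_no_events_no_factors(self):
        vocab = vocab_of([FeatureName.demo("age")])
        model = linear_model(vocab, {})
        report = explain(model, vocab, make_instance(events=[]))
        assert all(not entries for entries in report.factors.values())

    def test_negative_influences_excluded(self):
        model, vocab, inst = self.setup_model()
        report = explain(model, vocab, inst)
        codes = [e.code for e in report.factors["Diagnostic"]]
        assert codes == ["icd_a", "icd_b"]       # sorted by influence desc
        assert report.factors["Procedural"] == []  # negative weight -> excluded
        for entries in report.factors.values():
            assert all(e.influence > 0 for e in entries)
            assert [e.influence for e in entries] == sorted(
                (e.influence for e in entries), reverse=True)

    def test_observed_value_is_window_count(self):
        model, vocab, inst = self.setup_model()
        report = explain(model, vocab, inst)
        by_code = {e.code: e for e in report.factors["Diagnostic"]}
        assert by_code["icd_a"].value == 4

    def test_top_k_truncation(self):
        pd = 2000
        events = [ev("P1", pd - 1 - i, f"c{i}") for i in range(8)]
        inst = make_instance(pd=pd, events=events)
        names = [FeatureName.slice(ICD9, f"c{i}", 1) for i in range(8)]
        vocab = vocab_of(names)
        model = linear_model(vocab, {n: 0.1 * (i + 1)
                                     for i, n in enumerate(names)})
        report = explain(model, vocab, inst, top_k=5)
        assert len(report.factors["Diagnostic"]) == 5

    def test_report_byte_deterministic(self):
        model, vocab, inst = self.setup_model()
        a = explain(model, vocab, inst).to_json()
        b = explain(model, vocab, inst).to_json()
        assert a == b

    def test_text_table_mentions_all_reported_factors(self):
        model, vocab, inst = self.setup_model()
        report = explain(model, vocab, inst)
        text = report.to_text()
        assert "icd_a" in text and "Top Diagnostic factors" in text
        assert "Only factors that contributed" in text

    def test_stat_ablation_mode_adds_stat_factors(self):
        pd = 2000
        events = [ev("P1", pd - 1, "a"), ev("P1", pd - 2, "b")]
        inst = make_instance(pd=pd, events=events)
        names = [FeatureName.slice(ICD9, "a", 1), FeatureName.slice(ICD9, "b", 1),
                 FeatureName.stat(ICD9, "total_count")]
        vocab = vocab_of(names)
        model = linear_model(vocab, {names[2]: 0.4})
        report = explain(model, vocab, inst, include_stats=True)
        codes = [e.code for e in report.factors["Diagnostic"]]
        assert "total_count" in codes
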