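"""End-to-end orchestration: simulate -> cohort -> features -> model -> report.

Every stage logs its counts (patients in, instances selected, exclusions by
reason, features kept, snapshots taken, best validation AP) so each input
patient is accounted for, and all randomness flows from seeds recorded in
the run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import cohort as cohort_mod
from .cohort import CohortInstance, build_cohort, inpatient_spans, split_cohort
from .ehr import PatientRecord, read_event_log, write_event_log
from .features import FeatureMatrix, FeatureVocabulary, build_vocabulary, vectorize
from .metrics import evaluate
from .model import MLPMortalityClassifier, predict_probability, save_model
from .simulate import SimConfig, generate_population

log = logging.getLogger("palliascreen")


@dataclass
class PipelineConfig:
    """Configuration of a full run; seeds for every stage are explicit."""

    out_dir: str = "palliascreen_run"
    events_path: Optional[str] = None      # use an existing event log instead of simulating
    sim: SimConfig = field(default_factory=SimConfig)
    split_seed: int = 0
    split_ratios: tuple = (8, 1, 1)
    min_patient_support: int = 100
    model: dict = field(default_factory=dict)
    precision_targets: tuple = (0.9,)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        for key in ("split_ratios", "precision_targets"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive every stage seed from one master seed."""
        import dataclasses
        sim = dataclasses.replace(self.sim, seed=seed)
        model = dict(self.model, seed=seed + 1)
        return dataclasses.replace(self, sim=sim, split_seed=seed + 2, model=model)


# ------------------------------------------------------------- cohort I/O

def write_cohort(instances: Sequence[CohortInstance], table_path,
                 events_path) -> None:
    """Persist a cohort as an instance table plus a censored event log."""
    with open(table_path, "w", encoding="utf-8") as fh:
        fh.write("# patient_id\tprediction_date\tlabel\tadmitted\tdeath_date\t"
                 "followup_end\n")
        for inst in instances:
            death = "NA" if inst.death_date is None else str(inst.death_date)
            label = "NA" if inst.label is None else str(inst.label)
            fh.write(f"{inst.patient_id}\t{inst.prediction_date}\t{label}\t"
                     f"{int(inst.admitted)}\t{death}\t{inst.followup_end}\n")
    patients = [PatientRecord(inst.patient_id, inst.demographics,
                              inst.events, None) for inst in instances]
    write_event_log(patients, events_path)


def read_cohort(table_path, events_path) -> list[CohortInstance]:
    patients = {p.patient_id: p for p in read_event_log(events_path)}
    instances = []
    with open(table_path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            pid, pd_, label, admitted, death, follow = line.split("\t")
            p = patients[pid]
            instances.append(CohortInstance(
                patient_id=pid,
                prediction_date=int(pd_),
                label=None if label == "NA" else int(label),
                admitted=bool(int(admitted)),
                events=p.events,
                demographics=p.demographics,
                death_date=None if death == "NA" else int(death),
                followup_end=int(follow),
            ))
    return instances


# ------------------------------------------------------------- screening

def run_screen(model: MLPMortalityClassifier, vocabulary: FeatureVocabulary,
               patients: Sequence[PatientRecord],
               as_of_date: int) -> list[tuple[str, float]]:
    """Nightly screen: score every currently-admitted patient.

    Patients inside an inpatient admission at ``as_of_date`` with at least
    365 days of history are featurized with ``as_of_date`` as a label-free
    prediction date (record censored there) and returned sorted by
    descending probability (ties by patient_id).
    """
    candidates = []
    for p in patients:
        first = p.first_event_date()
        if first is None or as_of_date - first < 365:
            continue
        if not any(s <= as_of_date <= e for s, e in inpatient_spans(p)):
            continue
        candidates.append(CohortInstance(
            patient_id=p.patient_id, prediction_date=as_of_date, label=None,
            admitted=True,
            events=[ev for ev in p.events if ev.date <= as_of_date],
            demographics=p.demographics,
            death_date=None, followup_end=p.last_event_date()))
    if not candidates:
        return []
    fm = vectorize(candidates, vocabulary)
    probs = predict_probability(model, fm.X)
    ranked = sorted(zip(fm.row_ids, probs.tolist()), key=lambda t: (-t[1], t[0]))
    return ranked


# --------------------------------------------------------------- run_all

class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run summary.

    Artifacts written under ``config.out_dir``: the event log, the cohort
    table + censored event log, the vocabulary, train/val/test matrices,
    the trained model, the training log, the evaluation report and a run
    manifest with all counts and seeds.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seeds": {"sim": config.sim.seed, "split": config.split_seed,
                               "model": config.model.get("seed", 0)}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        name = stage("simulate")
        if config.events_path:
            patients = read_event_log(config.events_path)
        else:
            patients = generate_population(config.sim)
            write_event_log(patients, out / "events.tsv")
        summary["n_patients"] = len(patients)

        name = stage("build-cohort")
        instances, exclusions = build_cohort(patients, return_exclusions=True)
        write_cohort(instances, out / "cohort.tsv", out / "cohort_events.tsv")
        summary["n_instances"] = len(instances)
        summary["exclusions"] = dict(exclusions)
        summary["prevalence"] = (
            sum(i.label == 1 for i in instances) / len(instances)
            if instances else float("nan"))
        log.info("cohort: %d instances, excluded %s", len(instances),
                 dict(exclusions))

        name = stage("split")
        split = split_cohort(instances, config.split_ratios, config.split_seed)
        summary["split_sizes"] = {"train": len(split.train),
                                  "validation": len(split.validation),
                                  "test": len(split.test)}

        name = stage("featurize")
        vocab = build_vocabulary(split.train, config.min_patient_support)
        vocab.save(out / "vocabulary.txt")
        matrices = {part: vectorize(getattr(split, part), vocab)
                    for part in ("train", "validation", "test")}
        for part, fm in matrices.items():
            fm.save(out / f"{part}.mtx", out / f"{part}_rows.tsv")
        summary["n_features"] = len(vocab)
        log.info("vocabulary: %d features kept", len(vocab))

        name = stage("train")
        model = MLPMortalityClassifier(**config.model)
        model.fit(matrices["train"].X, matrices["train"].labels,
                  matrices["validation"].X, matrices["validation"].labels)
        save_model(model, out / "model.npz")
        with open(out / "training_log.tsv", "w", encoding="utf-8") as fh:
            fh.write("# iteration\tvalidation_ap\n")
            for it, ap in model.validation_ap_history_:
                fh.write(f"{it}\t{ap:.6f}\n")
        summary["n_snapshots"] = len(model.validation_ap_history_)
        summary["best_validation_ap"] = max(
            ap for _, ap in model.validation_ap_history_)
        log.info("training: %d snapshots, best validation AP %.3f",
                 summary["n_snapshots"], summary["best_validation_ap"])

        name = stage("evaluate")
        scores = predict_probability(model, matrices["test"].X)
        report = evaluate(scores, matrices["test"].labels,
                          precision_targets=config.precision_targets)
        with open(out / "evaluation.json", "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        summary["evaluation"] = {
            "ap": report.ap, "auroc": report.auroc, "brier": report.brier,
            "recall_at_precision": {str(k): v for k, v
                                    in report.recall_at_precision.items()}}
        log.info("test: AP %.3f AUROC %.3f Brier %.3f",
                 report.ap, report.auroc, report.brier)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc

    summary["runtime_seconds"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
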