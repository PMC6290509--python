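# Methods

## Problem framing

Twelve-month mortality is used as a proxy for palliative-care need. For a
patient with record history up to a *prediction date* (PD), the model
estimates `P(death within 365 days of PD)` from the coded events of the 365
days before PD. Framing the task this way requires care that the label
cannot leak into the features, which is what the cohort constraints below
enforce.

All dates in the package are integer day indices from an arbitrary epoch;
"3 months" is fixed at 90 days and "12 months" at 365 days. Age is
`floor((PD − birth_date)/365.25)` years.

## Cohort construction

Positives are patients with a recorded death date, negatives patients
without one. A feasible PD must be a recorded encounter date with at least
365 days of prior record, and additionally:

* positives: `death − 365 ≤ PD ≤ death − 90` — death must be near enough to
  predict but far enough for a referral to be useful;
* negatives: `last_event − PD ≥ 365` — survival for a full year past PD is
  certain within the record (guarding against deaths after the snapshot).

All interval bounds are inclusive. When any feasible date lies inside an
inpatient admission, selection is restricted to those dates
(filter-then-select, i.e. a lexicographic preference); the earliest
(positives) or latest (negatives) date is then chosen. If the chosen date
falls inside an admission the patient is flagged *admitted* and the PD is
moved to the admission's second day (day-one records are typically
incomplete); the move is re-verified against the case constraints and
rolled back (flag retained) if it breaks them, so the adjustment can never
invalidate a label. Patients with no feasible date are excluded and
counted, not errored. Events after PD are censored away. By construction
every positive dies 90–365 days after PD and every negative survives at
least 365, which the censor-length survival curves make visible as a
separation of the classes at t = 365.

The split is a patient-level multinomial draw at ratios 8:1:1 — sizes are
therefore approximate, matching the intent of a random partition rather
than an exact one.

## Featurization

The window `(PD−365, PD]` is partitioned into four half-open slices
`(PD−30, PD]`, `(PD−90, PD−30]`, `(PD−180, PD−90]`, `(PD−365, PD−180]`
(durations 30/60/90/185; recent history gets finer resolution). Events on
PD itself are in scope — censoring removes data strictly *after* PD.

Three feature families: per-slice code counts; per-category window summary
statistics (distinct codes, total events, and max / min / range / mean /
population-variance of the daily event tally, computed over *active* days
only — the "minimum non-zero per day" statistic forces the active-day
convention for the minimum and we apply it uniformly to mean and variance
for coherence); and demographics (numeric age, one-hot gender / race /
ethnicity with levels fixed by the training data). Encounter events
contribute counts per encounter type, so "number of inpatient days in the
window" arises naturally from the one-event-per-admitted-day convention of
the generator.

The vocabulary is built on the training split only (pruning on all data
would leak test-set support); slice/stat features occurring in ≤ 100
training patients are dropped, demographics always kept, and ordering is
lexicographic by serialized name for determinism. No standardization or
scaling is applied anywhere. Matrices are CSR; at the default study
conditions a row carries ~36 non-zeros against a few hundred columns.

## Model and training

A fully connected net maps the sparse feature vector through
`hidden_layers` SeLU layers of width `hidden_width` to a sigmoid output
trained on log loss (0 hidden layers = logistic regression). Optimization
is Adam at learning rate 0.001 with mini-batches of 128 and no explicit
regularization; instead, every 250 mini-batch iterations (and at the final
iteration) the current weights are scored by Average Precision on the
validation split, and the best snapshot is retroactively selected — the
earliest iteration on ties. AP is the selection metric because prevalence
is ~10%: with rare positives the precision-recall trade-off, not
sensitivity/specificity, determines whether acting on the ranked list is
worthwhile.

Weights use LeCun-normal initialization (He for ReLU); forward/backward
passes are straight numpy so sparse inputs stream through the first layer
without densification. Determinism: one seeded generator drives
initialization and shuffling; single-threaded runs reproduce the weight
trajectory and the AP history exactly on the same machine (bitwise
cross-platform identity is not promised). The default test-scale
configuration is 2×64; depth and width are configuration axes and the
full-scale 18×512 configuration is supported but is not exercised by the
test-suite, whose problem sizes (10,000 patients, 3,000 iterations) were
chosen so the whole study runs in minutes on one CPU.

## Evaluation

* **AP**: mean of precision at each positive's rank. Tied scores are
  treated as an exchangeable block and the reported value is the exact
  expectation over block orderings, computed in closed form (the positive
  at in-block rank *i* of a block with *k* positives among *m* items,
  preceded by *A* items of which *P* positive, contributes
  `(k/m)(P + 1 + (i−1)(k−1)/(m−1))/(A+i)`). Tests verify this against
  exhaustive enumeration of block placements.
* **AUROC**: Mann–Whitney probability with half-credit ties, via average
  ranks; brute-force pair counting is the test oracle.
* **PR curve**: raw points at every distinct threshold; interpolated
  precision is `max` precision over all points with recall ≥ r (the
  information-retrieval convention), which is non-increasing by
  construction. Recall-at-precision reads the largest recall whose
  interpolated precision meets the target. The scalar `ap` reported is the
  raw (non-interpolated) value; interpolation is used only for the curve
  and recall-at-precision.
* **Brier**: mean squared error of the probability. **Reliability**: 10
  equal-width right-closed bins; empty bins are kept with a zero count and
  NaN summaries rather than silently dropped.

## Explanation

Influence of a code = `log p(original) − log p(ablated)` (natural log; the
base rescales all influences equally and never changes rankings), where the
ablated instance has *every* occurrence of the code removed and all
features — including the summary statistics — recomputed from the reduced
event list. Recomputation matters: summary-statistic features can only
receive credit through the codes whose removal changes them. A standalone
stat-ablation mode (zeroing one stat feature at a time) exists but is off
by default. Only codes observed in the window are scored — perturbing
absent features answers a question about the population, not this patient —
which also bounds cost at O(distinct codes) forward passes. Probabilities
are clipped to `[1e-12, 1−1e-12]` before logs. Demographics: age set to 0,
gender swapped MALE↔FEMALE (patients with other gender identities are left
unperturbed, as are race and ethnicity). Reports keep the top 5
positive-influence factors per display category (Diagnostic, Procedural,
Medication, Encounter, Demographic), ties broken lexicographically.

## Synthetic data: what it does and does not emulate

The generator produces what the pipeline needs to be falsifiable: a known
mortality mechanism. Encounters arrive as a homogeneous Poisson process
(default 6/year over a 10-year span); each is an inpatient admission with
probability 0.03 (mean length 4 days, one ENCOUNTER/INPATIENT event per
admitted day) or a single OUTPATIENT/ER/SCAN event, and emits ~3 coded
events drawn uniformly from per-category vocabularies (300 ICD9, 200 CPT,
150 RXCUI). Five designated ICD9 risk codes with log-hazard effects
4.0/3.6/3.2/2.8/2.4 are each carried with probability 0.06; carriers remit
each code draw to a carried risk code with probability 0.4. Death is
exponential with annual hazard `0.002 · exp(Σ carried effects)`, recorded
iff inside the span. These defaults give a cohort prevalence of ~0.10 and
were fixed, before any model was trained, by the design requirement that a
univariate screen on the pooled risk-code count alone ranks deaths at
AUROC > 0.75 (measured: 0.85) — i.e. the planted signal is strong enough
that failure to recover it indicts the pipeline, not the data.

Hazard ratios of e^2.4–e^4.0 are the territory of metastatic-disease codes
against a low background hazard; they are deliberately at the clear end of
realistic so that signal recovery is a sharp test.

What the generator does *not* emulate: ICD/CPT semantics and hierarchy,
comorbidity correlation structure, coding-practice drift, utilization that
rises before death, age-dependent hazards, and realistic admission
frequency (because feasible prediction dates span ~8 years of encounters,
the *admitted* flag is set for a majority of synthetic patients, far above
the few percent a real warehouse yields). Passing tests therefore
demonstrate the pipeline's correctness and its ability to recover a planted
multiplicative-hazard signal — not clinical performance on real EHR data,
which depends on signal present in a real warehouse.

## Numerical conventions and degenerate inputs

* AP/PR require at least one positive; AUROC both classes — violations
  raise rather than return a default.
* Event-log readers return events in canonical (date, category, code,
  encounter_type) order, making parsing insensitive to row order; writers
  preserve the canonical order, so write∘read is the identity on
  canonically ordered populations.
* Unlabeled (screening-time) instances carry `label=None` and are encoded
  as −1 in matrix sidecars.
* An empty cohort splits into three empty lists; a patient with no events
  is excluded with reason `no_events`.
* Variance features use the population (biased) convention; `range = max −
  min_nonzero ≥ 0` always.

## Known limitations

Single-machine, in-memory design; no time-to-event modeling (the label is
binary by design); no hierarchy-aware code rollups or embeddings; no
confidence intervals on metrics; model persistence via `.npz` is a
convenience format, not a stable interchange format.
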