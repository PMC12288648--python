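# Methods

This note documents the models, rules, parameters and design choices
behind `respphen`, in the order data flows through the pipeline.

## Constructed concepts

Nine eICU-style source tables are consumed (Care Plan General, Infusion
Drug, Medication, Note, Nurse Care, Nurse Charting, Respiratory Care,
Respiratory Charting, Treatment). Each row is rendered into a
*constructed concept* — `Source = <table>; Concept = <v1>: <v2>: ...` —
with the table's descriptive columns joined with `": "` in a fixed order.
Numerics in chart values stay verbatim; the only normalization is that
trailing line breaks are dropped and internal line breaks collapse to one
space (so a concept always occupies a single line of a description).
Empty values are kept as empty strings: the mapping from field tuples to
text stays a bijection for line-break-free values, which keeps concept
identity well defined. Identity is exact case-sensitive string equality;
no vocabulary mapping, lowercasing or spell normalization is applied, so
two strings that differ in case are two concepts.

## Rule-based reference algorithm

The deterministic route applies, in order:

1. **First encounter per patient** (minimal unit-visit number; a
   duplicate (patient, order) pair is surfaced as an ambiguity error).
2. **Adults only**: age ≥ 18, the strict de-identification sentinel
   `>89` parsing as 90; unparseable ages are logged and excluded.
3. **Relevance filter**: records restricted to concepts in the lexicon's
   therapy and medication sets.
4. **Therapy criteria** (counting *records*, not distinct concepts):
   IMV requires ≥ 2 IMV records and ≥ 1 intubation-medication record
   (the medication co-requirement applies to IMV only); a noninvasive
   episode requires ≥ 2 NIPPV-or-HFNI records in total and is labeled
   HFNI when ≥ 1 of them is an HFNI concept, NIPPV when none are. The
   two noninvasive modalities share one episode: their criteria are
   defined jointly and this is the only reading under which both are
   simultaneously satisfiable. Episode spans are the min/max offsets of
   the supporting therapy records.
5. **IMV interval rule**: noninvasive records with offsets in the closed
   interval [first IMV record, last IMV record] are removed and the
   noninvasive criteria reassessed. The whole-span (not
   between-consecutive-records) interval is used; the rule is idempotent.
6. **Ordering**: no episode → `None`; one episode → `<therapy> Only`;
   noninvasive starting before IMV → a failure phenotype; IMV starting
   before noninvasive → an IMV-to-noninvasive phenotype. An exact
   start-offset tie between episodes, or any combination outside the
   eight classes, raises an explicit unclassifiable error rather than
   being silently coerced — arbitrary tie-breaking would corrupt ground
   truth.

## Backends, prompts, parsing

All classifiers sit behind one contract: `classify(template, payload) →
(raw text, parsed decision, latency seconds)`. Prompt templates are
editable YAML files with `{placeholder}` slots, an ordered
chain-of-thought question list, a final question whose parsed answer is
the decision, and an answer vocabulary. The shipped defaults use 3–4
chain-of-thought questions and the markers `FINAL ANSWER (YES or NO):`
and `FINAL PHENOTYPE:`; the parser keys off each template's own marker.
Parsing is deliberately forgiving of chain-of-thought text: it scans the
segment after the *last* occurrence of the marker (the whole text if the
marker is absent), matches vocabulary tokens case-insensitively on word
boundaries, and lets the last match win, longer tokens beating substrings
at the same position. No match yields the sentinel `UNPARSEABLE`, a
value rather than an exception, so downstream policy decides: concept
tasks default to treating it as NO (an unreadable response asserts no
relevance), the phenotype task defaults to raising, with a configurable
fallback label.

The live backend posts to an Ollama-style `/api/generate` endpoint over
stdlib HTTP with greedy decoding defaults (temperature 0.0, top-p 0.99)
chosen to keep responses inside the requested format, measures wall-clock
latency, and retries transient failures. Every backend can be wrapped in
a disk cache keyed by (model tag, SHA-256 of the assembled prompt);
reruns with an identical configuration replay entirely from cache.

The oracle backend answers concept prompts by set membership in the
generator's relevance lexicon and phenotype prompts by running the
reference rules over the description's (concept, rank) pairs. The noisy
backend flips each oracle decision independently with a configured
probability (binary tasks flip YES↔NO; the phenotype task moves to a
uniformly drawn different label), seeded for reproducibility.

## Concept selection and description phenotyping

Distinct concepts are classified once globally, each with two prompts
(therapies; medications), and selected when either answer is YES.
Selection iterates concepts in sorted text order, so results are
independent of input order; per-concept backend failures are collected
and only abort the stage past a configurable failure fraction (default
5%).

Per encounter, records are filtered to selected concepts and deduplicated
into a *constructed description*: each distinct concept once, numbered by
first-occurrence offset, rendered as `<rank>: <concept>` lines joined by
single line breaks. First-occurrence ties break lexicographically on
concept text so shuffled inputs give identical descriptions. Descriptions
carry no offsets or encounter identifiers, so identical texts are
interchangeable: each unique non-empty description is phenotyped with
exactly one backend call and the label mapped back to all encounters
sharing it. Empty descriptions are labeled `None` without a call — there
is no therapy evidence to present.

## Evaluation

Hard labels admit only the three-point ROC, so per-class one-vs-rest
AUROC is computed as (sensitivity + specificity)/2 — equivalently,
balanced accuracy — and the identity AUROC = (sens + spec)/2 holds
exactly by construction. Classes with zero true members are reported as
not applicable rather than 0 or 1. Macro averages are unweighted means
over two groups — {IMV Only, NIPPV Only, HFNI Only, None} and the four
multi-therapy sequence phenotypes — rounded to 3 decimals, which is the
precision at which group means of the published per-class values
reproduce (0.853 and 0.604 for the best model). Latency summaries are
arithmetic means per prompt and pooled over all calls, so the pooled mean
equals the call-count-weighted mean of per-prompt means.

## Synthetic cohort generator

The generator emulates an adult-ICU registry extract at the level the
pipeline consumes: nine delimited tables with eICU column names
(`patientunitstayid`, per-table offset columns in integer minutes from
ICU admission, negative offsets permitted), a patient table, and a
planted-truth sidecar.

Defaults are fixed to the registry conditions the package targets:

* **phenotype mix** — the reported cohort composition (10.48% IMV Only,
  4.28% NIPPV Only, 0.68% HFNI Only, 0.92% NIPPV Failure, 0.36% HFNI
  Failure, 0.38% IMV to NIPPV, 0.12% IMV to HFNI, 82.79% None, from the
  published per-phenotype encounter counts out of 159,701);
* **extra encounters** — Poisson(0.2074) repeat encounters per patient,
  matching the reported 200,859 encounters across 166,355 patients, so
  the first-encounter filter does real work;
* **distractor rate** — mean 20 irrelevant records per encounter
  (Poisson), a deliberately modest stand-in for the bulk of routine
  charting; not stated by any source and chosen once;
* **minors** 5% and **`>89` sentinel** 3%, chosen once to exercise the
  age filter and sentinel parsing.

Planted relevant records use pairwise-distinct concepts at
pairwise-distinct offsets (one record per concept), with sequence
phenotypes laid out so the first therapy's offsets strictly precede the
second's. This invariant is what makes exact end-to-end oracle
equivalence provable: descriptions deduplicate concepts and replace
offsets with ranks, and with one record per concept the rank order is a
strictly monotone image of the offset order, so therapy counting and the
interval rule agree between the record level and the description level.
Real data do not have this property — the same device string is charted
repeatedly, so a description-level classifier genuinely sees less than
the record-level rules do. Passing oracle tests therefore demonstrates
the pipeline's plumbing is lossless and the stages compose correctly,
not that description-level phenotyping matches record-level rules on
arbitrary real extracts. The shipped relevance lexicon (26 therapy, 10
medication, 40 distractor concepts modeled on real charting strings) is
small and fully overridable; the four sets are validated pairwise
disjoint, so concept ground truth is unambiguous. `balanced_concept_
sample` inflates numbered concept variants for accuracy studies at
arbitrary size.

Numerical/determinism choices: all randomness flows through one
`numpy` generator per cohort, fixed seeds give bit-identical output, and
every stage is order-invariant in its inputs (sorting by offset, text, or
id before any decision). Distractor offsets may collide with relevant
offsets or each other; relevant offsets never collide.

## Problem sizes used in the checks

The shipped checks run cohorts of 120–500 patients (the end-to-end oracle
check uses 500, yielding ~480 evaluated encounters), a 5,000-patient
cohort for the phenotype-mix chi-square check, and 10,000 balanced
concepts for the noise-degradation check; these sizes give comfortable
Monte-Carlo resolution for the properties asserted while keeping the
whole suite fast.

## Known limitations

* AUROC from hard labels cannot exceed balanced accuracy; score-based
  ROC analysis is out of scope because the backends emit discrete
  decisions only.
* The generator does not emulate vocabulary drift, misspellings,
  multi-ICU transfers, or concept strings shared across therapy
  categories; distractors are drawn from a closed list.
* Encounters whose surviving episodes exceed one transition (possible in
  principle on real data, never in planted data) are surfaced as
  unclassifiable errors, not forced into a class.
* The live backend is a thin client: no model hosting, sampling-based
  self-consistency, or GPU management.
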