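# respphen

Computational phenotyping of ICU encounters by the **respiratory-support
therapies** they received — invasive mechanical ventilation (IMV),
noninvasive positive pressure ventilation (NIPPV), and high-flow nasal
insufflation (HFNI) — from raw eICU-style EHR tables.

The package is written for informatics researchers who build and validate
computable phenotypes for acute respiratory failure cohorts. It implements
two routes to the same eight-phenotype classification and the harness to
compare them:

1. a **deterministic rule-based reference algorithm** (cohort filters,
   record-count therapy criteria, an IMV interval rule, sequence ordering),
   usable as ground truth;
2. a **language-model-backed pipeline** — constructed-concept generation,
   chain-of-thought concept selection with two prompts OR-combined,
   constructed-description phenotyping with deduplication — behind a
   pluggable backend contract with oracle, noisy, and live (Ollama-style
   HTTP) backends;

plus a **synthetic EHR generator** that plants known phenotypes into
eICU-shaped tables, so every stage is testable offline without access to
restricted clinical data.

## The classification

Encounters are labeled with one of eight phenotypes:

> IMV Only · NIPPV Only · HFNI Only · NIPPV Failure (NIPPV→IMV) ·
> HFNI Failure (HFNI→IMV) · IMV to NIPPV · IMV to HFNI · None

Therapy receipt is decided by record counts over a relevance lexicon of
constructed concepts (strings of the form
`Source = <table>; Concept = <values>` built from nine source tables):

* **IMV** — ≥ 2 records indicating IMV **and** ≥ 1 record indicating an
  intubation-related medication;
* **noninvasive** — ≥ 2 records indicating NIPPV or HFNI, labeled HFNI when
  at least one is an HFNI concept, NIPPV otherwise.

When IMV is present, noninvasive records inside the closed interval
[first IMV record, last IMV record] are removed and the noninvasive
criteria reassessed. Surviving episodes are ordered by start offset
(minutes from ICU admission) to name the phenotype.

Because the pipeline's classifiers emit hard labels, per-class one-vs-rest
AUROC is the three-point-ROC trapezoid, which equals
(sensitivity + specificity) / 2; macro averages are unweighted means over
phenotype groups.

## Worked example

Generate a 200-patient synthetic cohort and run the full pipeline with the
oracle backend (which answers prompts from the generator's own relevance
lexicon, so it should reproduce the reference labels exactly):

```python
from pathlib import Path
from respphen.pipeline import RunConfig, run_pipeline
from respphen.synthetic import GeneratorConfig

cfg = RunConfig(
    seed=11,
    tables_dir="demo/tables",
    out_dir="demo/out",
    generator=GeneratorConfig(n_patients=200, seed=11),
)
report = run_pipeline(cfg)
print("\n".join(report.summary_lines()))
```

prints

```
encounters evaluated: 193
phenotype         n_true  n_pred   AUROC    sens    spec
IMV Only              21      21   1.000   1.000   1.000
NIPPV Only             8       8   1.000   1.000   1.000
HFNI Only              1       1   1.000   1.000   1.000
NIPPV Failure          1       1   1.000   1.000   1.000
HFNI Failure           1       1   1.000   1.000   1.000
IMV to NIPPV           1       1   1.000   1.000   1.000
IMV to HFNI            -       -     n/a     n/a     n/a
None                 160     160   1.000   1.000   1.000
macro AUROC [single_therapy_and_none]: 1.000
macro AUROC [multi_therapy]: 1.000
mean_therapy_seconds: 0.0
mean_medication_seconds: 0.0
mean_overall_seconds: 0.0
n_calls: 152
```

Reading the output: 200 patients yielded 193 encounters that survive the
first-encounter and adult filters; the phenotype mix follows the default
(realistic, heavily `None`-skewed) cohort composition; every per-class
AUROC/sensitivity/specificity is 1.0 because the oracle backend is exact,
and `IMV to HFNI` is reported n/a rather than 0 or 1 because no true case
of it was drawn at this cohort size. 152 prompts were answered (two per
distinct constructed concept).

The same run is available from the shell:

```bash
respphen generate --n-patients 200 --seed 11 --out demo/tables
respphen run-all --config run.yaml          # keys mirror RunConfig
respphen reference-phenotype --tables demo/tables --out labels.csv
```

Swap `backend: {kind: noisy, flip_prob: 0.1}` into the run configuration
to study how accuracy degrades under imperfect concept decisions, or
`kind: live` with an endpoint and model tag to drive a local model
(responses are cached on disk by model tag and prompt hash, so reruns make
no new calls).

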