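"""Run configuration and end-to-end pipeline orchestration.

The pipeline executes the stages in order — (optional) synthetic cohort
generation, table reading, concept construction, concept selection,
description building, description phenotyping, evaluation — and writes
each stage's artifact to the output directory stamped with the
configuration hash and seed, so two runs with equal configuration are
byte-identical for the deterministic backends.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field

from . import describe, io, selection
from .backends import (
    CachedBackend,
    DecodingSettings,
    LiveBackend,
    NoisyBackend,
    OracleBackend,
    default_templates,
)
from .concepts import distinct_concepts
from .reference import filter_adults, phenotype_encounter, select_first_encounters
from .evaluation import EvalReport, evaluate_labels
from .synthetic import (
    GeneratorConfig,
    default_lexicon,
    generate_cohort,
    load_lexicon,
    read_truths,
    write_tables,
)

__all__ = ["BackendConfig", "PolicyConfig", "RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class BackendConfig(BaseModel):
    kind: Literal["oracle", "noisy", "live"] = "oracle"
    flip_prob: float = Field(default=0.1, ge=0.0, le=1.0)
    latency_seconds: float = Field(default=0.0, ge=0.0)
    decoding: DecodingSettings = Field(default_factory=DecodingSettings)


class PolicyConfig(BaseModel):
    unparseable_concept: Literal["YES", "NO"] = "NO"
    unparseable_phenotype: str = "error"  # 'error' or a fallback label
    failure_threshold: float = Field(default=0.05, ge=0.0, le=1.0)


class RunConfig(BaseModel):
    """Structured run configuration (YAML on disk)."""

    seed: int = 0
    tables_dir: str
    out_dir: str
    lexicon_path: str | None = None
    template_dir: str | None = None
    cache_dir: str | None = None
    backend: BackendConfig = Field(default_factory=BackendConfig)
    policies: PolicyConfig = Field(default_factory=PolicyConfig)
    generator: GeneratorConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        # hash the scientific configuration; output/cache locations are
        # placement, not content decisions
        dump = self.model_dump(mode="json", exclude={"out_dir", "cache_dir"})
        return hashlib.sha256(json.dumps(dump, sort_keys=True).encode()).hexdigest()[:12]


def _make_backend(config: RunConfig, lexicon):
    bc = config.backend
    if bc.kind == "oracle":
        backend = OracleBackend(lexicon, bc.latency_seconds)
    elif bc.kind == "noisy":
        backend = NoisyBackend(lexicon, bc.flip_prob, config.seed, bc.latency_seconds)
    else:
        backend = LiveBackend(bc.decoding)
    if config.cache_dir:
        backend = CachedBackend(backend, Path(config.cache_dir))
    return backend


def _stamp(config: RunConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute the full pipeline and write artifacts under ``out_dir``.

    Validates paths and templates before any stage runs; a stage failure
    leaves the artifacts of completed stages intact. Ground truth for
    evaluation is the planted truth file when present, otherwise the
    rule-based reference algorithm applied to the same records.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    templates = default_templates(config.template_dir)  # validates before any stage
    lexicon = load_lexicon(config.lexicon_path) if config.lexicon_path else default_lexicon()

    tables_dir = Path(config.tables_dir)
    if config.generator is not None and not (tables_dir / "patient.csv").exists():
        gen = config.generator.model_copy(update={"seed": config.seed, "lexicon": lexicon})
        records, encounters, truths = generate_cohort(gen)
        write_tables(records, encounters, tables_dir, truths)
        logger.info("generated %d records across %d encounters", len(records), len(encounters))

    records, encounters = io.read_tables(tables_dir)
    cohort = filter_adults(select_first_encounters(encounters))
    cohort_ids = {e.encounter_id for e in cohort}
    by_encounter: dict[str, list] = {eid: [] for eid in cohort_ids}
    for r in records:
        if r.encounter_id in cohort_ids:
            by_encounter[r.encounter_id].append(r)
    logger.info("cohort: %d of %d encounters after filters", len(cohort), len(encounters))

    backend = _make_backend(config, lexicon)

    # --- concept selection over all distinct concepts
    concepts = distinct_concepts(records)
    sel = selection.select_concepts(
        concepts,
        backend,
        templates,
        unparseable_as=config.policies.unparseable_concept,
        failure_threshold=config.policies.failure_threshold,
    )
    logger.info("selected %d of %d distinct concepts", len(sel.selected), len(concepts))
    with (out / "concept_decisions.jsonl").open("w") as fh:
        fh.write(_stamp(config))
        for d in sel.decisions:
            fh.write(
                json.dumps(
                    {
                        "concept": d.concept.text,
                        "therapy": d.therapy_decision,
                        "medication": d.medication_decision,
                        "final": d.final,
                        "latencies": d.latency_map(),
                    }
                )
                + "\n"
            )
    (out / "selected_concepts.txt").write_text(
        _stamp(config) + "\n".join(sorted(sel.selected_texts)) + "\n"
    )

    # --- constructed descriptions, deduplicated phenotyping
    selected_texts = sel.selected_texts
    enc_desc = {
        eid: describe.build_description(recs, selected_texts)
        for eid, recs in by_encounter.items()
    }
    desc_labels = describe.phenotype_descriptions(
        enc_desc.values(),
        backend,
        templates["phenotype"],
        unparseable=config.policies.unparseable_phenotype,
    )
    pred = describe.map_to_encounters(
        desc_labels, {eid: d.text for eid, d in enc_desc.items()}
    )
    n_unique = len({d.text for d in enc_desc.values()})
    logger.info("phenotyped %d unique descriptions for %d encounters", n_unique, len(pred))
    with (out / "encounter_labels.csv").open("w") as fh:
        fh.write(_stamp(config))
        fh.write("patientunitstayid,phenotype,description_sha1\n")
        for eid in sorted(pred):
            fh.write(f"{eid},{pred[eid]},{enc_desc[eid].digest()}\n")

    # --- ground truth: planted truths if available, else the reference rules
    truths_path = tables_dir / "truths.jsonl"
    if truths_path.exists():
        truth = {
            t.encounter_id: t.phenotype
            for t in read_truths(truths_path)
            if t.encounter_id in cohort_ids
        }
    else:
        truth = {eid: phenotype_encounter(recs, lexicon) for eid, recs in by_encounter.items()}

    latencies = {"therapy": [], "medication": []}
    for d in sel.decisions:
        for name, secs in d.latencies:
            latencies[name].append(secs)
    report = evaluate_labels(pred, truth, latencies)
    report_payload = {"config_hash": config.config_hash(), "seed": config.seed, **report.to_dict()}
    (out / "report.json").write_text(json.dumps(report_payload, indent=2) + "\n")
    (out / "summary.txt").write_text(_stamp(config) + "\n".join(report.summary_lines()) + "\n")
    return report
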