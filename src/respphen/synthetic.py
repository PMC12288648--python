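"""Synthetic eICU-style cohorts with planted respiratory-support phenotypes.

Real ICU EHR extracts of this shape are access-restricted, so every
downstream stage is exercised against generated cohorts in which the
true phenotype of each encounter is planted by construction: an
encounter's relevant records are laid out so that the rule-based
reference algorithm provably recovers the intended label, and irrelevant
"distractor" records are interleaved at random offsets to emulate the
bulk of ordinary charting.

Two properties are deliberately engineered into planted data:

* every relevant record uses a distinct concept at a distinct offset, so
  the deduplicated, offset-free constructed description of an encounter
  retains everything the phenotype depends on;
* the three relevant concept sets and the distractor set are pairwise
  disjoint, so concept-level ground truth is unambiguous.

The generator also emits non-first encounters and under-18 encounters
(flagged in the planted truths) so the cohort filters are exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .concepts import TABLES, RawRecord, parse_concept_text
from .reference import NONE_LABEL, PHENOTYPES, Encounter, parse_age

__all__ = [
    "RelevanceLexicon",
    "GeneratorConfig",
    "PlantedTruth",
    "default_lexicon",
    "load_lexicon",
    "save_lexicon",
    "plant_phenotype",
    "generate_cohort",
    "write_tables",
    "balanced_concept_sample",
    "record_for_concept",
]


# ---------------------------------------------------------------------------
# lexicon


@dataclass(frozen=True)
class RelevanceLexicon:
    """Ground-truth concept relevance used for planting and for the oracle.

    ``therapy_concepts`` maps each therapy (IMV/NIPPV/HFNI) to a set of
    constructed-concept texts indicating it; ``medication_concepts`` are
    intubation-related medications; ``distractor_concepts`` are relevant
    to nothing. The four sets must be pairwise disjoint.
    """

    therapy_concepts: dict[str, frozenset[str]]
    medication_concepts: frozenset[str]
    distractor_concepts: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.therapy_concepts[t] for t in ("IMV", "NIPPV", "HFNI")]
        sets += [self.medication_concepts, self.distractor_concepts]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("lexicon concept sets must be pairwise disjoint")

    def relevant_concepts(self) -> frozenset[str]:
        return (
            self.therapy_concepts["IMV"]
            | self.therapy_concepts["NIPPV"]
            | self.therapy_concepts["HFNI"]
            | self.medication_concepts
        )

    def therapy_of(self, text: str) -> str | None:
        for therapy, concepts in self.therapy_concepts.items():
            if text in concepts:
                return therapy
        return None


def _cc(table: str, *values: str) -> str:
    return f"Source = {table}; Concept = {': '.join(values)}"


_DEFAULT_IMV = (
    _cc("Nurse Charting", "O2 Admin Device", "Ventilator"),
    _cc("Respiratory Care", "Oral ETT"),
    _cc("Respiratory Care", "Nasal ETT"),
    _cc("Respiratory Care", "Tracheostomy"),
    _cc("Respiratory Charting", "respFlowSettings", "Tidal Volume (set)", "450"),
    _cc("Respiratory Charting", "respFlowSettings", "PEEP", "5"),
    _cc("Respiratory Charting", "respFlowPtVentData", "Plateau Pressure", "24"),
    _cc("Treatment", "pulmonary|ventilation and oxygenation|mechanical ventilation"),
    _cc("Care Plan General", "Airway", "Intubated/oral ETT"),
    _cc("Note", "Intubation", "intubated with 7.5 ETT, placement confirmed"),
)

_DEFAULT_NIPPV = (
    _cc("Nurse Charting", "O2 Admin Device", "BiPAP/CPAP"),
    _cc("Nurse Charting", "Non-Invasive Vent Status", "BiPAP in use"),
    _cc("Respiratory Charting", "respFlowSettings", "NIV Mode", "S/T"),
    _cc("Respiratory Charting", "respFlowSettings", "EPAP", "5"),
    _cc("Respiratory Charting", "respFlowSettings", "IPAP", "12"),
    _cc("Treatment", "pulmonary|ventilation and oxygenation|non-invasive ventilation"),
    _cc("Treatment", "pulmonary|ventilation and oxygenation|CPAP/PEEP therapy"),
    _cc("Care Plan General", "Ventilation", "Non-invasive ventilation"),
    _cc("Note", "Respiratory Support", "patient placed on BiPAP overnight"),
)

_DEFAULT_HFNI = (
    _cc("Nurse Charting", "O2 Admin Device", "Hi Flow NC"),
    _cc("Nurse Charting", "O2 Admin Device", "HFNC"),
    _cc("Nurse Charting", "O2 Admin Device", "high flow nasal cannula"),
    _cc("Respiratory Charting", "respFlowSettings", "HFNC Flow Rate", "40"),
    _cc("Respiratory Charting", "respFlowSettings", "Heated High Flow", "50 L/min"),
    _cc("Treatment", "pulmonary|ventilation and oxygenation|oxygen therapy (> 60% oxygen)|high flow nasal cannula"),
    _cc("Care Plan General", "Oxygen Therapy", "High flow nasal insufflation"),
)

_DEFAULT_MEDS = (
    _cc("Medication", "SUCCINYLCHOLINE 20 MG/ML VIAL"),
    _cc("Medication", "ROCURONIUM 10 MG/ML VIAL"),
    _cc("Medication", "ETOMIDATE 2 MG/ML VIAL"),
    _cc("Medication", "VECURONIUM 1 MG/ML VIAL"),
    _cc("Medication", "KETAMINE 500 MG/10 ML VIAL"),
    _cc("Infusion Drug", "Propofol (mcg/kg/min)"),
    _cc("Infusion Drug", "Fentanyl (mcg/hr)"),
    _cc("Infusion Drug", "Midazolam (mg/hr)"),
    _cc("Infusion Drug", "Dexmedetomidine (mcg/kg/hr)"),
    _cc("Infusion Drug", "Cisatracurium (mcg/kg/min)"),
)

_DEFAULT_DISTRACTORS = (
    _cc("Medication", "LOPRESSOR"),
    _cc("Medication", "ASPIRIN 81 MG TAB"),
    _cc("Medication", "LISINOPRIL 10 MG TAB"),
    _cc("Medication", "METFORMIN 500 MG TAB"),
    _cc("Medication", "WARFARIN 5 MG TAB"),
    _cc("Medication", "PANTOPRAZOLE 40 MG TAB"),
    _cc("Infusion Drug", "Amiodarone (mg/min)"),
    _cc("Infusion Drug", "Norepinephrine (mcg/min)"),
    _cc("Infusion Drug", "Insulin (units/hr)"),
    _cc("Infusion Drug", "Heparin (units/hr)"),
    _cc("Care Plan General", "Route-Status", "Oral - low sodium"),
    _cc("Care Plan General", "Activity", "Bedrest"),
    _cc("Care Plan General", "Safety/Restraints", "Fall precautions"),
    _cc("Care Plan General", "Psychosocial Status", "Comfortable"),
    _cc("Note", "denies fevers", "denies fevers"),
    _cc("Note", "Admission Note", "admitted from ED with chest pain"),
    _cc("Note", "Social History", "former smoker, quit 10 years ago"),
    _cc("Note", "Family Contact", "spouse at bedside"),
    _cc("Nurse Care", "emergency equipment at bedside"),
    _cc("Nurse Care", "skin intact"),
    _cc("Nurse Care", "turned and repositioned"),
    _cc("Nurse Care", "call light within reach"),
    _cc("Nurse Charting", "Heart Rate", "88"),
    _cc("Nurse Charting", "Pain Score", "3"),
    _cc("Nurse Charting", "Temperature (F)", "98.6"),
    _cc("Nurse Charting", "O2 Saturation", "97"),
    _cc("Nurse Charting", "Respiratory Rate", "18"),
    _cc("Nurse Charting", "Glasgow coma score", "15"),
    _cc("Nurse Charting", "Bedside Glucose", "132"),
    _cc("Nurse Charting", "O2 Admin Device", "nasal cannula"),
    _cc("Respiratory Care", "None documented"),
    _cc("Respiratory Charting", "respFlowPtVentData", "SaO2", "25"),
    _cc("Respiratory Charting", "respFlowPtVentData", "RR (patient)", "22"),
    _cc("Treatment", "cardiovascular—myocardial ischemia / infarction—antiplatelet agent—aspirin"),
    _cc("Treatment", "renal|electrolyte correction|potassium"),
    _cc("Treatment", "neurologic|pain / agitation|analgesics"),
    _cc("Treatment", "gastrointestinal|nutrition|enteral feeds"),
    _cc("Treatment", "endocrine|glucose metabolism|sliding scale insulin"),
    _cc("Treatment", "infectious diseases|medications|systemic antibiotics"),
    _cc("Treatment", "cardiovascular|hypertension|beta-blocker"),
)


def default_lexicon() -> RelevanceLexicon:
    """The shipped relevance lexicon: ~30 therapy, 10 medication and 40
    distractor concepts modeled on real eICU charting strings."""
    return RelevanceLexicon(
        therapy_concepts={
            "IMV": frozenset(_DEFAULT_IMV),
            "NIPPV": frozenset(_DEFAULT_NIPPV),
            "HFNI": frozenset(_DEFAULT_HFNI),
        },
        medication_concepts=frozenset(_DEFAULT_MEDS),
        distractor_concepts=frozenset(_DEFAULT_DISTRACTORS),
    )


def load_lexicon(path: str | Path) -> RelevanceLexicon:
    data = yaml.safe_load(Path(path).read_text())
    return RelevanceLexicon(
        therapy_concepts={t: frozenset(data["therapy_concepts"][t]) for t in ("IMV", "NIPPV", "HFNI")},
        medication_concepts=frozenset(data["medication_concepts"]),
        distractor_concepts=frozenset(data.get("distractor_concepts", ())),
    )


def save_lexicon(lexicon: RelevanceLexicon, path: str | Path) -> None:
    data = {
        "therapy_concepts": {t: sorted(lexicon.therapy_concepts[t]) for t in ("IMV", "NIPPV", "HFNI")},
        "medication_concepts": sorted(lexicon.medication_concepts),
        "distractor_concepts": sorted(lexicon.distractor_concepts),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# configuration


#: Reported cohort composition of the source registry: encounter counts per
#: phenotype out of 159,701 first, adult encounters.
_REFERENCE_COUNTS = {
    "IMV Only": 16736,
    "NIPPV Only": 6833,
    "HFNI Only": 1089,
    "NIPPV Failure": 1466,
    "HFNI Failure": 568,
    "IMV to NIPPV": 601,
    "IMV to HFNI": 186,
    NONE_LABEL: 132222,
}


def reference_phenotype_mix() -> dict[str, float]:
    total = sum(_REFERENCE_COUNTS.values())
    return {k: v / total for k, v in _REFERENCE_COUNTS.items()}


class GeneratorConfig(BaseModel):
    """Cohort-generation parameters.

    Defaults emulate the published registry cohort: the phenotype mix is
    its reported per-phenotype encounter fractions, and the extra-encounter
    rate reproduces its 1.207 encounters per patient. ``distractor_rate``
    is the mean number of irrelevant records per encounter.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_patients: int = Field(gt=0)
    phenotype_mix: dict[str, float] = Field(default_factory=reference_phenotype_mix)
    distractor_rate: float = Field(default=20.0, ge=0.0)
    extra_encounter_rate: float = Field(default=0.2074, ge=0.0)
    minor_probability: float = Field(default=0.05, ge=0.0, le=1.0)
    elder_sentinel_probability: float = Field(default=0.03, ge=0.0, le=1.0)
    seed: int = 0
    lexicon: RelevanceLexicon | None = Field(default=None, exclude=True, repr=False)

    @property
    def lexicon_obj(self) -> RelevanceLexicon:
        return self.lexicon if self.lexicon is not None else default_lexicon()

    @field_validator("phenotype_mix")
    @classmethod
    def _valid_mix(cls, mix: dict[str, float]) -> dict[str, float]:
        unknown = set(mix) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotype(s) in mix: {sorted(unknown)}")
        if any(p < 0 for p in mix.values()):
            raise ValueError("phenotype_mix probabilities must be non-negative")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"phenotype_mix must sum to 1, got {sum(mix.values()):.6f}")
        return mix

    @model_validator(mode="after")
    def _freeze_order(self) -> "GeneratorConfig":
        # canonical label order makes sampling independent of dict insertion order
        self.phenotype_mix = {p: self.phenotype_mix.get(p, 0.0) for p in PHENOTYPES}
        return self


@dataclass(frozen=True)
class PlantedTruth:
    """The label an encounter was generated to carry.

    ``included`` marks encounters that survive the first-encounter and
    adult filters; labels of excluded encounters are still planted but
    carry no evaluation weight.
    """

    encounter_id: str
    phenotype: str
    episode_offsets: dict[str, tuple[int, ...]]
    included: bool


# ---------------------------------------------------------------------------
# planting


def record_for_concept(text: str, offset: int, encounter_id: str) -> RawRecord:
    table, fields = parse_concept_text(text)
    return RawRecord.make(encounter_id, table, offset, **fields)


def _pick(rng: np.random.Generator, pool: frozenset[str], k: int) -> list[str]:
    items = sorted(pool)
    idx = rng.choice(len(items), size=k, replace=False)
    return [items[i] for i in sorted(idx)]


def plant_phenotype(
    phenotype: str,
    lexicon: RelevanceLexicon,
    rng: np.random.Generator,
    encounter_id: str = "",
) -> tuple[list[RawRecord], dict[str, tuple[int, ...]]]:
    """Records whose relevant-concept content satisfies exactly *phenotype*.

    Relevant records use pairwise-distinct concepts at pairwise-distinct
    offsets; for sequence phenotypes the first therapy's offsets all
    strictly precede the second's, so the episode order is unambiguous
    under the reference rules (including the IMV interval rule). Returns
    the records and the per-therapy offsets used.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")

    tc = lexicon.therapy_concepts

    def counts_for(pool: frozenset[str], lo: int, hi: int) -> int:
        return int(rng.integers(lo, min(hi, len(pool)) + 1))

    # choose which concepts participate, grouped by therapy/medication
    groups: list[tuple[str, list[str]]] = []  # (role, concepts) in temporal order
    meds: list[str] = []
    if phenotype == "IMV Only":
        groups = [("IMV", _pick(rng, tc["IMV"], counts_for(tc["IMV"], 2, 4)))]
        meds = _pick(rng, lexicon.medication_concepts, counts_for(lexicon.medication_concepts, 1, 2))
    elif phenotype == "NIPPV Only":
        groups = [("NIPPV", _pick(rng, tc["NIPPV"], counts_for(tc["NIPPV"], 2, 4)))]
    elif phenotype == "HFNI Only":
        n_h = counts_for(tc["HFNI"], 1, 2)
        n_n = int(rng.integers(max(0, 2 - n_h), 3))
        mix = _pick(rng, tc["HFNI"], n_h) + _pick(rng, tc["NIPPV"], n_n)
        groups = [("HFNI", mix)]
    elif phenotype in ("NIPPV Failure", "HFNI Failure"):
        first = "NIPPV" if phenotype == "NIPPV Failure" else "HFNI"
        if first == "NIPPV":
            noninv = _pick(rng, tc["NIPPV"], counts_for(tc["NIPPV"], 2, 3))
        else:
            n_h = counts_for(tc["HFNI"], 1, 2)
            noninv = _pick(rng, tc["HFNI"], n_h) + _pick(rng, tc["NIPPV"], int(rng.integers(max(0, 2 - n_h), 3)))
        groups = [(first, noninv), ("IMV", _pick(rng, tc["IMV"], counts_for(tc["IMV"], 2, 4)))]
        meds = _pick(rng, lexicon.medication_concepts, counts_for(lexicon.medication_concepts, 1, 2))
    elif phenotype in ("IMV to NIPPV", "IMV to HFNI"):
        second = "NIPPV" if phenotype == "IMV to NIPPV" else "HFNI"
        if second == "NIPPV":
            noninv = _pick(rng, tc["NIPPV"], counts_for(tc["NIPPV"], 2, 3))
        else:
            n_h = counts_for(tc["HFNI"], 1, 2)
            noninv = _pick(rng, tc["HFNI"], n_h) + _pick(rng, tc["NIPPV"], int(rng.integers(max(0, 2 - n_h), 3)))
        groups = [("IMV", _pick(rng, tc["IMV"], counts_for(tc["IMV"], 2, 4))), (second, noninv)]
        meds = _pick(rng, lexicon.medication_concepts, counts_for(lexicon.medication_concepts, 1, 2))
    elif phenotype == NONE_LABEL:
        # sub-qualifying evidence: nothing, a lone therapy record, IMV
        # records without medication, or a stray medication
        case = int(rng.integers(0, 4))
        if case == 1:
            pool = tc[("IMV", "NIPPV", "HFNI")[int(rng.integers(0, 3))]]
            groups = [("stray", _pick(rng, pool, 1))]
        elif case == 2:
            groups = [("stray", _pick(rng, tc["IMV"], 2))]
        elif case == 3:
            meds = _pick(rng, lexicon.medication_concepts, 1)

    # distinct offsets for every relevant record, block-ordered for sequences
    seq_concepts = [c for _, cs in groups for c in cs]
    n_offsets = len(seq_concepts) + len(meds)
    offsets = np.sort(rng.choice(4000, size=n_offsets, replace=False)) + 1  # 1..4000
    seq_offsets, med_offsets = offsets[: len(seq_concepts)], offsets[len(seq_concepts):]

    records: list[RawRecord] = []
    episode_offsets: dict[str, list[int]] = {}
    i = 0
    for role, concepts in groups:
        # within a block, shuffle which concept gets which offset
        block = seq_offsets[i : i + len(concepts)]
        i += len(concepts)
        perm = rng.permutation(len(concepts))
        for j, off in zip(perm, block):
            records.append(record_for_concept(concepts[j], int(off), encounter_id))
            episode_offsets.setdefault(role, []).append(int(off))
    for text, off in zip(meds, med_offsets):
        records.append(record_for_concept(text, int(off), encounter_id))
        episode_offsets.setdefault("medication", []).append(int(off))
    return records, {k: tuple(v) for k, v in episode_offsets.items()}


# ---------------------------------------------------------------------------
# cohort generation


def _distractor_records(
    lexicon: RelevanceLexicon, rng: np.random.Generator, rate: float, encounter_id: str
) -> list[RawRecord]:
    pool = sorted(lexicon.distractor_concepts)
    if not pool or rate <= 0:
        return []
    n = int(rng.poisson(rate))
    out = []
    for _ in range(n):
        text = pool[int(rng.integers(0, len(pool)))]
        off = int(rng.integers(-60, 5001))
        out.append(record_for_concept(text, off, encounter_id))
    return out


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[RawRecord], list[Encounter], list[PlantedTruth]]:
    """Generate a labeled cohort.

    Each patient receives one first encounter plus Poisson-distributed
    repeat encounters; each encounter gets a phenotype drawn from the
    configured mix, the corresponding planted relevant records, and
    Poisson-many distractor records at random offsets. Fixed seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(config.phenotype_mix)
    probs = np.array([config.phenotype_mix[p] for p in labels])

    records: list[RawRecord] = []
    encounters: list[Encounter] = []
    truths: list[PlantedTruth] = []
    enc_counter = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:06d}"
        n_enc = 1 + int(rng.poisson(config.extra_encounter_rate))
        for order in range(1, n_enc + 1):
            enc_counter += 1
            encounter_id = f"E{enc_counter:07d}"
            if rng.random() < config.minor_probability:
                age = str(int(rng.integers(1, 18)))
            elif rng.random() < config.elder_sentinel_probability:
                age = ">89"
            else:
                age = str(int(rng.integers(18, 90)))
            phenotype = labels[int(rng.choice(len(labels), p=probs))]
            planted, episode_offsets = plant_phenotype(phenotype, config.lexicon_obj, rng, encounter_id)
            planted += _distractor_records(config.lexicon_obj, rng, config.distractor_rate, encounter_id)
            included = order == 1 and (parse_age(age) or 0) >= 18
            records.extend(planted)
            encounters.append(Encounter(encounter_id, patient_id, age, order))
            truths.append(PlantedTruth(encounter_id, phenotype, episode_offsets, included))
    return records, encounters, truths


# ---------------------------------------------------------------------------
# table output


def write_tables(
    records: list[RawRecord],
    encounters: list[Encounter],
    out_dir: str | Path,
    truths: list[PlantedTruth] | None = None,
) -> list[Path]:
    """Write the cohort as one delimited file per source table.

    Files use eICU-style column names: ``patientunitstayid`` for the
    encounter id and the table-specific offset column. Also writes
    ``patient.csv`` (encounter/patient/age/visit order) and, when truths
    are given, ``truths.jsonl``. Round-trips through ``io.read_tables``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    by_table: dict[str, list[RawRecord]] = {name: [] for name in TABLES}
    for r in records:
        by_table[r.table].append(r)
    for name, spec in TABLES.items():
        rows = [
            {"patientunitstayid": r.encounter_id, spec.offset_col: r.offset_minutes, **r.field_map()}
            for r in by_table[name]
        ]
        df = pd.DataFrame(rows, columns=["patientunitstayid", spec.offset_col, *spec.fields])
        path = out / f"{spec.file_stem}.csv"
        df.to_csv(path, index=False)
        paths.append(path)

    pat = pd.DataFrame(
        [
            {
                "patientunitstayid": e.encounter_id,
                "uniquepid": e.patient_id,
                "age": e.age,
                "unitvisitnumber": e.admit_order,
            }
            for e in encounters
        ],
        columns=["patientunitstayid", "uniquepid", "age", "unitvisitnumber"],
    )
    pat_path = out / "patient.csv"
    pat.to_csv(pat_path, index=False)
    paths.append(pat_path)

    if truths is not None:
        tpath = out / "truths.jsonl"
        with tpath.open("w") as fh:
            for t in truths:
                fh.write(
                    json.dumps(
                        {
                            "encounter_id": t.encounter_id,
                            "phenotype": t.phenotype,
                            "episode_offsets": {k: list(v) for k, v in t.episode_offsets.items()},
                            "included": t.included,
                        }
                    )
                    + "\n"
                )
        paths.append(tpath)
    return paths


def read_truths(path: str | Path) -> list[PlantedTruth]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        out.append(
            PlantedTruth(
                d["encounter_id"],
                d["phenotype"],
                {k: tuple(v) for k, v in d["episode_offsets"].items()},
                d["included"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# concept-level benchmark sets


def balanced_concept_sample(
    n: int, seed: int
) -> tuple[RelevanceLexicon, list[str], dict[str, bool]]:
    """A balanced concept benchmark: *n* concept texts, half relevant.

    Relevant texts are numbered variants planted into the therapy and
    medication sets of an inflated lexicon; the other half are numbered
    distractors. Used for concept-selection accuracy studies at sizes
    far beyond the shipped lexicon.
    """
    if n % 2:
        raise ValueError("n must be even for a balanced sample")
    rng = np.random.default_rng(seed)
    half = n // 2
    n_med = half // 4
    n_ther = half - n_med
    therapies = ("IMV", "NIPPV", "HFNI")
    templates = {
        "IMV": ("Nurse Charting", "Vent Setting", "mode variant {i}"),
        "NIPPV": ("Nurse Charting", "O2 Admin Device", "BiPAP mask variant {i}"),
        "HFNI": ("Nurse Charting", "O2 Admin Device", "high flow unit {i}"),
    }
    ther_sets: dict[str, set[str]] = {t: set() for t in therapies}
    for i in range(n_ther):
        t = therapies[i % 3]
        tbl, a, b = templates[t]
        ther_sets[t].add(_cc(tbl, a, b.format(i=i)))
    meds = {_cc("Medication", f"INDUCTION AGENT {i} VIAL") for i in range(n_med)}
    distractors = {_cc("Nurse Charting", "Routine Observation", f"value {i}") for i in range(half)}
    lex = RelevanceLexicon(
        therapy_concepts={t: frozenset(ther_sets[t]) for t in therapies},
        medication_concepts=frozenset(meds),
        distractor_concepts=frozenset(distractors),
    )
    texts = sorted(lex.relevant_concepts()) + sorted(distractors)
    truth = {t: t in lex.relevant_concepts() for t in texts}
    order = rng.permutation(len(texts))
    texts = [texts[i] for i in order]
    return lex, texts, truth
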