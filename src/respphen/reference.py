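"""Deterministic rule-based phenotyping of respiratory-support therapies.

One ICU encounter is classified into one of eight phenotypes by the type
and order of respiratory-support therapies received:

    IMV Only, NIPPV Only, HFNI Only, NIPPV Failure, HFNI Failure,
    IMV to NIPPV, IMV to HFNI, None

Therapy receipt criteria (counting *records*, not distinct concepts):

* IMV — at least two records whose concept is an IMV concept AND at
  least one record whose concept is an intubation-related medication.
* a noninvasive therapy — at least two records whose concepts are NIPPV
  or HFNI concepts; the episode is labeled HFNI when at least one of
  them is an HFNI concept, NIPPV when none are. (The two noninvasive
  modalities share one episode because their criteria are defined
  jointly; this is the only reading under which both are satisfiable.)

When an IMV episode exists, noninvasive records with offsets inside the
closed IMV span [first IMV record, last IMV record] are discarded and
the noninvasive criteria reassessed. The surviving episodes are ordered
by start offset to name the phenotype; an exact start-offset tie between
episodes is surfaced as an error rather than broken arbitrarily.

This module is the ground truth the language-model stages are evaluated
against; it is deliberately free of any randomness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .concepts import RawRecord, build_concept

__all__ = [
    "PHENOTYPES",
    "THERAPIES",
    "NONE_LABEL",
    "TherapyEpisode",
    "Encounter",
    "AmbiguityError",
    "UnclassifiableError",
    "select_first_encounters",
    "parse_age",
    "filter_adults",
    "detect_therapies",
    "apply_imv_interval_rule",
    "classify_phenotype",
    "phenotype_encounter",
    "phenotype_concept_sequence",
]

logger = logging.getLogger(__name__)

THERAPIES: tuple[str, ...] = ("IMV", "NIPPV", "HFNI")
NONE_LABEL = "None"
PHENOTYPES: tuple[str, ...] = (
    "IMV Only",
    "NIPPV Only",
    "HFNI Only",
    "NIPPV Failure",
    "HFNI Failure",
    "IMV to NIPPV",
    "IMV to HFNI",
    NONE_LABEL,
)

#: Minimum supporting-record counts per therapy episode.
MIN_RECORDS = {"IMV": 2, "NIPPV": 2, "HFNI": 2}


@dataclass(frozen=True)
class Encounter:
    """One ICU stay; the unit of phenotyping."""

    encounter_id: str
    patient_id: str
    age: str  # integer string or the sentinel ">89"
    admit_order: int  # 1-based rank within the patient's history


@dataclass(frozen=True)
class TherapyEpisode:
    therapy: str
    start_offset: int
    end_offset: int
    supporting_record_count: int

    def __post_init__(self) -> None:
        if self.therapy not in THERAPIES:
            raise ValueError(f"unknown therapy {self.therapy!r}")
        if self.start_offset > self.end_offset:
            raise ValueError("episode start after end")
        if self.supporting_record_count < MIN_RECORDS[self.therapy]:
            raise ValueError(
                f"{self.therapy} episode needs >= {MIN_RECORDS[self.therapy]} supporting records"
            )


class AmbiguityError(ValueError):
    """Duplicate (patient, admit_order) pairs make first-encounter choice ambiguous."""


class UnclassifiableError(ValueError):
    """Episode combination has no home in the eight-phenotype set."""


# ---------------------------------------------------------------------------
# cohort filters


def select_first_encounters(encounters: Sequence[Encounter]) -> list[Encounter]:
    """Keep exactly one encounter per patient: the minimal admit_order."""
    best: dict[str, Encounter] = {}
    for enc in encounters:
        prev = best.get(enc.patient_id)
        if prev is None or enc.admit_order < prev.admit_order:
            best[enc.patient_id] = enc
        elif enc.admit_order == prev.admit_order and enc.encounter_id != prev.encounter_id:
            raise AmbiguityError(
                f"patient {enc.patient_id}: encounters {prev.encounter_id} and "
                f"{enc.encounter_id} share admit_order {enc.admit_order}"
            )
    return [best[pid] for pid in sorted(best)]


def parse_age(age: str) -> int | None:
    """Age in whole years; the de-identification sentinel ``>89`` parses as 90."""
    s = str(age).strip()
    if s == ">89":
        return 90
    try:
        return int(s)
    except ValueError:
        return None


def filter_adults(encounters: Sequence[Encounter]) -> list[Encounter]:
    """Drop encounters for patients under 18 at the start of the encounter.

    Unparseable ages are logged and excluded — an encounter whose age
    cannot be established never enters the cohort.
    """
    kept = []
    for enc in encounters:
        age = parse_age(enc.age)
        if age is None:
            logger.warning("encounter %s: unparseable age %r, excluded", enc.encounter_id, enc.age)
            continue
        if age >= 18:
            kept.append(enc)
    return kept


# ---------------------------------------------------------------------------
# therapy detection on (concept text, offset) pairs

Pair = tuple[str, int]


def _detect_from_pairs(pairs: Sequence[Pair], lexicon) -> list[TherapyEpisode]:
    imv = [off for text, off in pairs if text in lexicon.therapy_concepts["IMV"]]
    nippv = [off for text, off in pairs if text in lexicon.therapy_concepts["NIPPV"]]
    hfni = [off for text, off in pairs if text in lexicon.therapy_concepts["HFNI"]]
    meds = sum(1 for text, _ in pairs if text in lexicon.medication_concepts)

    episodes: list[TherapyEpisode] = []
    if len(imv) >= MIN_RECORDS["IMV"] and meds >= 1:
        episodes.append(TherapyEpisode("IMV", min(imv), max(imv), len(imv)))
    noninv = nippv + hfni
    if len(noninv) >= 2:
        label = "HFNI" if hfni else "NIPPV"
        episodes.append(TherapyEpisode(label, min(noninv), max(noninv), len(noninv)))
    return episodes


def _imv_episode(episodes: Iterable[TherapyEpisode]) -> TherapyEpisode | None:
    return next((e for e in episodes if e.therapy == "IMV"), None)


def _strip_interval_pairs(pairs: Sequence[Pair], imv: TherapyEpisode, lexicon) -> list[Pair]:
    noninv = lexicon.therapy_concepts["NIPPV"] | lexicon.therapy_concepts["HFNI"]
    return [
        (text, off)
        for text, off in pairs
        if not (text in noninv and imv.start_offset <= off <= imv.end_offset)
    ]


def _classify_pairs(pairs: Sequence[Pair], lexicon) -> str:
    episodes = _detect_from_pairs(pairs, lexicon)
    imv = _imv_episode(episodes)
    if imv is not None:
        pairs = _strip_interval_pairs(pairs, imv, lexicon)
        episodes = _detect_from_pairs(pairs, lexicon)
    return classify_phenotype(episodes)


# ---------------------------------------------------------------------------
# record-level operations


def detect_therapies(records: Sequence[RawRecord], lexicon) -> list[TherapyEpisode]:
    """Therapy episodes supported by *records* of one encounter.

    Records are assumed pre-filtered to the selected (relevant) concepts.
    Episode start/end are the min/max offsets of the supporting therapy
    records; the medication co-requirement applies to IMV only.
    """
    pairs = [(build_concept(r).text, r.offset_minutes) for r in records]
    return _detect_from_pairs(pairs, lexicon)


def apply_imv_interval_rule(
    records: Sequence[RawRecord], imv_episode: TherapyEpisode, lexicon
) -> list[RawRecord]:
    """Drop noninvasive records inside the closed IMV span.

    Records whose concept is a NIPPV or HFNI concept and whose offset
    lies in [imv start, imv end] are removed; everything else is kept.
    Idempotent, and the identity when *imv_episode* is None.
    """
    if imv_episode is None:
        return list(records)
    noninv = lexicon.therapy_concepts["NIPPV"] | lexicon.therapy_concepts["HFNI"]
    out = []
    for r in records:
        text = build_concept(r).text
        if text in noninv and imv_episode.start_offset <= r.offset_minutes <= imv_episode.end_offset:
            continue
        out.append(r)
    return out


def classify_phenotype(episodes: Sequence[TherapyEpisode]) -> str:
    """Name the phenotype from post-interval-rule episodes.

    No episodes -> ``None``; a single episode -> ``<therapy> Only``; an
    IMV episode plus a noninvasive one is ordered by start offset into a
    failure (noninvasive first) or an IMV-to-noninvasive sequence. Any
    other combination — including an exact start-offset tie — raises
    :class:`UnclassifiableError` rather than coercing silently.
    """
    eps = list(episodes)
    if not eps:
        return NONE_LABEL
    if len(eps) == 1:
        return f"{eps[0].therapy} Only"
    if len(eps) == 2:
        imv = _imv_episode(eps)
        other = next((e for e in eps if e.therapy != "IMV"), None)
        if imv is None or other is None:
            raise UnclassifiableError(
                f"two episodes of {sorted(e.therapy for e in eps)} have no phenotype"
            )
        if imv.start_offset == other.start_offset:
            raise UnclassifiableError(
                f"IMV and {other.therapy} episodes tie at start offset {imv.start_offset}"
            )
        if other.start_offset < imv.start_offset:
            return f"{other.therapy} Failure"
        return f"IMV to {other.therapy}"
    raise UnclassifiableError(f"{len(eps)} episodes exceed the two-episode phenotype space")


def phenotype_encounter(records: Sequence[RawRecord], lexicon) -> str:
    """Full per-encounter pipeline: filter to relevant concepts, detect
    therapies, apply the IMV interval rule, classify."""
    relevant = lexicon.relevant_concepts()
    pairs = [
        (text, r.offset_minutes)
        for r in records
        if (text := build_concept(r).text) in relevant
    ]
    return _classify_pairs(pairs, lexicon)


def phenotype_concept_sequence(pairs: Sequence[Pair], lexicon) -> str:
    """Classify an encounter from (concept text, position) pairs.

    Identical rules to :func:`phenotype_encounter`, but over already-built
    concept texts with any strictly order-preserving positions (offsets,
    or first-occurrence ranks of a constructed description). Used by the
    oracle backend, which sees descriptions rather than raw records.
    """
    relevant = lexicon.relevant_concepts()
    return _classify_pairs([(t, o) for t, o in pairs if t in relevant], lexicon)
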