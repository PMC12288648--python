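"""Constructed descriptions and description-level phenotyping.

An encounter's *constructed description* is the ordered, deduplicated
list of its selected concepts: each distinct concept appears once,
numbered by the order of its first occurrence after ICU admission and
rendered as ``<rank>: <concept>`` lines. Timestamps are generalized to
concept order and no encounter identifiers appear, so identical
descriptions are interchangeable — they are phenotyped once and the
label is mapped back to every encounter sharing the text.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .backends import UNPARSEABLE, PromptTemplate
from .concepts import RawRecord, build_concept
from .reference import NONE_LABEL, PHENOTYPES

__all__ = [
    "ConstructedDescription",
    "IntegrityError",
    "UnparseablePhenotypeError",
    "build_description",
    "phenotype_descriptions",
    "map_to_encounters",
]


class IntegrityError(RuntimeError):
    """An encounter is missing its description entry."""


class UnparseablePhenotypeError(RuntimeError):
    """A phenotype response could not be parsed and the policy is 'error'."""


@dataclass(frozen=True)
class ConstructedDescription:
    """Rank-numbered concept lines; ``text`` is the prompt payload."""

    lines: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        ranks = [r for r, _ in self.lines]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError("ranks must be 1..n with no gaps")
        texts = [t for _, t in self.lines]
        if len(set(texts)) != len(texts):
            raise ValueError("concepts must be distinct within a description")

    @property
    def text(self) -> str:
        return "\n".join(f"{rank}: {concept}" for rank, concept in self.lines)

    @property
    def empty(self) -> bool:
        return not self.lines

    def digest(self) -> str:
        return hashlib.sha1(self.text.encode()).hexdigest()


def build_description(
    records: Sequence[RawRecord], selected_concepts: Iterable[str]
) -> ConstructedDescription:
    """Description of one encounter from its records and the selected set.

    Records whose concept is not selected are dropped; each surviving
    distinct concept is ranked by its minimum offset, ties broken by
    lexicographic concept text so shuffled inputs give identical output.
    An encounter with no selected concept yields an empty description.
    """
    selected = {c if isinstance(c, str) else c.text for c in selected_concepts}
    first_seen: dict[str, int] = {}
    for r in records:
        text = build_concept(r).text
        if text not in selected:
            continue
        if text not in first_seen or r.offset_minutes < first_seen[text]:
            first_seen[text] = r.offset_minutes
    ordered = sorted(first_seen, key=lambda t: (first_seen[t], t))
    return ConstructedDescription(tuple((i + 1, t) for i, t in enumerate(ordered)))


def phenotype_descriptions(
    descriptions: Iterable[ConstructedDescription],
    backend,
    template: PromptTemplate,
    unparseable: str = "error",
) -> dict[str, str]:
    """Phenotype each unique description text with one backend call.

    Empty descriptions are labeled ``None`` without a call — there is no
    therapy evidence to present. Parsed labels must belong to the
    eight-phenotype set; unparseable responses either raise (policy
    ``'error'``, the default) or take the policy string as their label.
    Returns a map from description text to label.
    """
    unique: dict[str, ConstructedDescription] = {}
    for d in descriptions:
        unique.setdefault(d.text, d)
    labels: dict[str, str] = {}
    for text, desc in unique.items():
        if desc.empty:
            labels[text] = NONE_LABEL
            continue
        resp = backend.classify(template, text)
        decision = resp.decision
        if decision == UNPARSEABLE or decision not in PHENOTYPES:
            if unparseable == "error":
                raise UnparseablePhenotypeError(
                    f"unparseable phenotype response for description {desc.digest()}: "
                    f"{resp.raw_text[:200]!r}"
                )
            decision = unparseable
        labels[text] = decision
    return labels


def map_to_encounters(
    desc_labels: Mapping[str, str], encounter_descriptions: Mapping[str, str]
) -> dict[str, str]:
    """Map description-level labels back onto encounters.

    *encounter_descriptions* maps encounter id to description text; a
    missing label for any encounter's description is an integrity error.
    Total and deterministic.
    """
    out = {}
    for encounter_id, text in encounter_descriptions.items():
        if text not in desc_labels:
            raise IntegrityError(f"encounter {encounter_id} has no phenotyped description")
        out[encounter_id] = desc_labels[text]
    return out
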