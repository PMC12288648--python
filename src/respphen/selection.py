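"""Concept selection: two prompts per distinct concept, OR-combined.

Every distinct constructed concept in a dataset is classified twice —
once against the respiratory-support-therapy prompt and once against the
intubation-medication prompt — and is *selected* when at least one of
the two decisions is YES. Concepts are classified once globally (not per
encounter); decisions are joined back to records by exact concept text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .backends import UNPARSEABLE, ClassifierResponse, PromptTemplate
from .concepts import ConstructedConcept

__all__ = [
    "ConceptDecision",
    "SelectionResult",
    "StageFailureError",
    "classify_concept",
    "select_concepts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConceptDecision:
    concept: ConstructedConcept
    therapy_decision: str
    medication_decision: str
    final: str  # YES | NO
    latencies: tuple[tuple[str, float], ...]  # (prompt name, seconds)
    raw_texts: tuple[tuple[str, str], ...] = ()

    def latency_map(self) -> dict[str, float]:
        return dict(self.latencies)


class StageFailureError(RuntimeError):
    """Backend failure fraction exceeded the configured threshold."""


def _resolve(decision: str, unparseable_as: str) -> str:
    return unparseable_as if decision == UNPARSEABLE else decision


def classify_concept(
    concept: ConstructedConcept,
    backend,
    templates: Mapping[str, PromptTemplate],
    unparseable_as: str = "NO",
) -> ConceptDecision:
    """Two backend calls (therapy, medication) OR-combined into a final
    YES/NO. Unparseable responses resolve per *unparseable_as* (default
    NO: a response that cannot be read asserts no relevance)."""
    responses: dict[str, ClassifierResponse] = {}
    for name in ("therapy", "medication"):
        try:
            responses[name] = backend.classify(templates[name], concept.text)
        except Exception as e:
            raise type(e)(f"concept {concept.text!r} ({name} prompt): {e}") from e
    therapy = _resolve(responses["therapy"].decision, unparseable_as)
    medication = _resolve(responses["medication"].decision, unparseable_as)
    final = "YES" if "YES" in (therapy, medication) else "NO"
    return ConceptDecision(
        concept=concept,
        therapy_decision=therapy,
        medication_decision=medication,
        final=final,
        latencies=tuple((n, responses[n].latency_seconds) for n in ("therapy", "medication")),
        raw_texts=tuple((n, responses[n].raw_text) for n in ("therapy", "medication")),
    )


@dataclass
class SelectionResult:
    selected: set[ConstructedConcept]
    decisions: list[ConceptDecision]
    failures: list[tuple[ConstructedConcept, str]]

    @property
    def selected_texts(self) -> set[str]:
        return {c.text for c in self.selected}

    def latency_summary(self) -> dict[str, float]:
        from .evaluation import latency_summary

        by_prompt: dict[str, list[float]] = {"therapy": [], "medication": []}
        for d in self.decisions:
            for name, secs in d.latencies:
                by_prompt[name].append(secs)
        return latency_summary(by_prompt)


def select_concepts(
    concepts: Iterable[ConstructedConcept],
    backend,
    templates: Mapping[str, PromptTemplate],
    unparseable_as: str = "NO",
    failure_threshold: float = 0.05,
    progress: bool = False,
) -> SelectionResult:
    """Classify every distinct concept and return the YES set.

    Per-concept backend failures are collected rather than fatal; the
    stage aborts with :class:`StageFailureError` only when the failure
    fraction exceeds *failure_threshold*. Deterministic in the concept
    set: concepts are processed in sorted text order, so results are
    independent of input order.
    """
    ordered = sorted(set(concepts), key=lambda c: c.text)
    iterator = ordered
    if progress:
        from tqdm import tqdm

        iterator = tqdm(ordered, desc="concept selection", unit="concept")
    decisions: list[ConceptDecision] = []
    failures: list[tuple[ConstructedConcept, str]] = []
    for concept in iterator:
        try:
            decisions.append(classify_concept(concept, backend, templates, unparseable_as))
        except Exception as e:
            logger.warning("concept classification failed: %s", e)
            failures.append((concept, str(e)))
    if ordered and len(failures) / len(ordered) > failure_threshold:
        raise StageFailureError(
            f"{len(failures)}/{len(ordered)} concept classifications failed "
            f"(threshold {failure_threshold:.0%})"
        )
    selected = {d.concept for d in decisions if d.final == "YES"}
    return SelectionResult(selected=selected, decisions=decisions, failures=failures)
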