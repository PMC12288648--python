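"""Classification backends: prompt assembly, answer parsing, test doubles.

Every stage that needs a text classifier talks to a *backend* through one
method, ``classify(template, payload) -> ClassifierResponse``, so the
pipeline's outputs depend on a backend only through its parsed decision
and latency. Three backends ship:

* :class:`OracleBackend` — answers from the ground-truth relevance
  lexicon (concept tasks) or the rule-based reference algorithm
  (phenotype task); enables exact end-to-end verification.
* :class:`NoisyBackend` — the oracle with seeded independent decision
  flips, for accuracy-degradation studies.
* :class:`LiveBackend` — an HTTP client for an Ollama-style local model
  endpoint, with greedy decoding defaults (temperature 0.0, top-p 0.99)
  chosen to keep responses inside the requested format.

Responses can be wrapped in a :class:`CachedBackend`, which persists raw
texts on disk keyed by (model tag, prompt hash) so reruns issue no new
calls.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field

from .reference import PHENOTYPES, phenotype_concept_sequence

__all__ = [
    "UNPARSEABLE",
    "PromptTemplate",
    "DecodingSettings",
    "ClassifierResponse",
    "TemplateError",
    "BackendError",
    "assemble_prompt",
    "parse_final_answer",
    "load_template",
    "default_template_dir",
    "default_templates",
    "OracleBackend",
    "NoisyBackend",
    "LiveBackend",
    "CachedBackend",
]

UNPARSEABLE = "UNPARSEABLE"

TASKS = ("concept-therapy", "concept-medication", "phenotype")


class TemplateError(ValueError):
    pass


class BackendError(RuntimeError):
    """A live call failed after the configured retries."""


@dataclass(frozen=True)
class PromptTemplate:
    """A prompt skeleton with a chain-of-thought question sequence.

    ``preamble`` carries ``{placeholder}`` slots (one of them ``{payload}``),
    ``cot_questions`` are intermediate reasoning questions emitted in
    order, and the parsed answer to ``final_question`` — the last line of
    the prompt — is the decision. ``answer_marker`` is the string the
    parser keys off in the response; it defaults to the final question.
    """

    task: str
    preamble: str
    cot_questions: tuple[str, ...]
    final_question: str
    answer_vocabulary: tuple[str, ...]
    placeholders: tuple[tuple[str, str], ...] = ()
    answer_marker: str | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise TemplateError(f"unknown task {self.task!r}")
        if not self.final_question:
            raise TemplateError("final_question is required")
        if not self.answer_vocabulary:
            raise TemplateError("answer_vocabulary must be non-empty")

    @property
    def marker(self) -> str:
        return self.answer_marker or self.final_question


class DecodingSettings(BaseModel):
    """Decoding and endpoint settings for live models."""

    temperature: float = Field(default=0.0, ge=0.0)
    top_p: float = Field(default=0.99, gt=0.0, le=1.0)
    max_tokens: int = Field(default=1024, gt=0)
    model_name: str = "mistral-small:24b"
    endpoint: str = "http://localhost:11434/api/generate"
    timeout_seconds: float = Field(default=120.0, gt=0)
    retries: int = Field(default=2, ge=0)


@dataclass(frozen=True)
class ClassifierResponse:
    raw_text: str
    decision: str
    latency_seconds: float

    def __post_init__(self) -> None:
        if self.latency_seconds < 0:
            raise ValueError("latency must be non-negative")


_PLACEHOLDER = re.compile(r"\{([a-z_]+)\}")


def assemble_prompt(template: PromptTemplate, payload: str) -> str:
    """Substitute *payload* (and any template placeholders) into the prompt.

    The payload slot must occur exactly once, chain-of-thought questions
    keep their order, and the final question is the last line.
    """
    if template.preamble.count("{payload}") != 1:
        raise TemplateError("preamble must contain {payload} exactly once")
    text = template.preamble
    mapping = dict(template.placeholders)
    mapping["payload"] = payload
    for name, value in mapping.items():
        text = text.replace("{" + name + "}", value)
    leftover = _PLACEHOLDER.search(text)
    if leftover:
        raise TemplateError(f"unresolved placeholder {{{leftover.group(1)}}}")
    parts = [text.rstrip("\n")]
    if template.cot_questions:
        parts.append("\n".join(template.cot_questions))
    parts.append(template.final_question)
    return "\n\n".join(parts)


def parse_final_answer(raw_text: str, template: PromptTemplate) -> str:
    """Parse a backend's raw text into a decision.

    Looks in the segment after the last (case-insensitive) occurrence of
    the template's answer marker — or the whole text if the marker is
    absent — for answer-vocabulary tokens; the last match wins, longer
    tokens beating shorter ones at the same position. No match yields
    :data:`UNPARSEABLE` (a value, never an exception).
    """
    lower = raw_text.lower()
    idx = lower.rfind(template.marker.lower())
    segment = lower[idx + len(template.marker):] if idx >= 0 else lower
    best: tuple[int, int] | None = None
    best_token = UNPARSEABLE
    for token in template.answer_vocabulary:
        # word-boundary match so e.g. "cannot" never matches "no"
        pattern = r"(?<![a-z])" + re.escape(token.lower()) + r"(?![a-z])"
        for m in re.finditer(pattern, segment):
            key = (m.start(), len(token))
            if best is None or key > best:
                best, best_token = key, token
    return best_token


# ---------------------------------------------------------------------------
# template files


def load_template(path: str | Path) -> PromptTemplate:
    """Load a YAML template file (editable structured text with
    ``{placeholder}`` slots)."""
    data = yaml.safe_load(Path(path).read_text())
    try:
        return PromptTemplate(
            task=data["task"],
            preamble=data["preamble"],
            cot_questions=tuple(data.get("cot_questions", ())),
            final_question=data["final_question"],
            answer_vocabulary=tuple(str(v) for v in data["answer_vocabulary"]),
            placeholders=tuple(sorted(dict(data.get("placeholders", {})).items())),
            answer_marker=data.get("answer_marker"),
        )
    except KeyError as e:  # pragma: no cover - exercised via TemplateError path
        raise TemplateError(f"template {path} missing required key {e}") from e


def default_template_dir() -> Path:
    return Path(__file__).parent / "templates"


_TEMPLATE_FILES = {
    "therapy": "concept_therapy.yaml",
    "medication": "concept_medication.yaml",
    "phenotype": "phenotype.yaml",
}


def default_templates(template_dir: str | Path | None = None) -> dict[str, PromptTemplate]:
    """The shipped (or a user-supplied) template trio keyed by
    'therapy', 'medication', 'phenotype'."""
    d = Path(template_dir) if template_dir is not None else default_template_dir()
    out = {}
    for key, fname in _TEMPLATE_FILES.items():
        path = d / fname
        if not path.exists():
            raise TemplateError(f"missing template file {path}")
        out[key] = load_template(path)
    return out


# ---------------------------------------------------------------------------
# backends


def _extract_description_pairs(payload: str) -> list[tuple[str, int]]:
    """Recover (concept text, rank) pairs from a constructed description."""
    pairs = []
    for line in payload.splitlines():
        m = re.fullmatch(r"(\d+): (.*)", line)
        if m:
            pairs.append((m.group(2), int(m.group(1))))
    return pairs


class OracleBackend:
    """Ground-truth test double.

    Concept tasks answer YES iff the payload concept is in the relevant
    set for the task's category; the phenotype task runs the reference
    algorithm over the description's (concept, rank) pairs. Raw text is
    rendered in the model-response shape (reasoning line, then the
    marker and the answer) so parsing is exercised for real.
    """

    cache_tag = "oracle"

    def __init__(self, lexicon, latency_seconds: float = 0.0) -> None:
        self.lexicon = lexicon
        self.latency_seconds = latency_seconds
        self.calls = 0

    def _decide(self, template: PromptTemplate, payload: str) -> str:
        if template.task == "concept-therapy":
            relevant = (
                self.lexicon.therapy_concepts["IMV"]
                | self.lexicon.therapy_concepts["NIPPV"]
                | self.lexicon.therapy_concepts["HFNI"]
            )
            return "YES" if payload in relevant else "NO"
        if template.task == "concept-medication":
            return "YES" if payload in self.lexicon.medication_concepts else "NO"
        pairs = _extract_description_pairs(payload)
        return phenotype_concept_sequence(pairs, self.lexicon)

    def classify(self, template: PromptTemplate, payload: str) -> ClassifierResponse:
        self.calls += 1
        answer = self._decide(template, payload)
        raw = f"Reviewing the input step by step.\n{template.marker} {answer}"
        return ClassifierResponse(raw, parse_final_answer(raw, template), self.latency_seconds)


class NoisyBackend:
    """Oracle with seeded independent decision flips at rate *flip_prob*.

    Binary tasks flip YES<->NO; the phenotype task moves to a uniformly
    chosen different label. flip_prob 0 reproduces the oracle exactly.
    """

    def __init__(self, lexicon, flip_prob: float, seed: int, latency_seconds: float = 0.0) -> None:
        if not 0.0 <= flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        self._oracle = OracleBackend(lexicon, latency_seconds)
        self.flip_prob = flip_prob
        self._rng = np.random.default_rng(seed)
        self.cache_tag = f"noisy-{flip_prob}-{seed}"

    @property
    def calls(self) -> int:
        return self._oracle.calls

    def classify(self, template: PromptTemplate, payload: str) -> ClassifierResponse:
        resp = self._oracle.classify(template, payload)
        if self._rng.random() >= self.flip_prob:
            return resp
        if template.task == "phenotype":
            others = [p for p in PHENOTYPES if p != resp.decision]
            answer = others[int(self._rng.integers(0, len(others)))]
        else:
            answer = "NO" if resp.decision == "YES" else "YES"
        raw = f"Reviewing the input step by step.\n{template.marker} {answer}"
        return ClassifierResponse(raw, parse_final_answer(raw, template), resp.latency_seconds)


class LiveBackend:
    """HTTP client for an Ollama-style ``/api/generate`` endpoint.

    Sends the assembled prompt with the configured decoding settings,
    measures wall-clock latency, and retries transient failures before
    raising :class:`BackendError`. Unparseable responses are preserved
    (decision UNPARSEABLE) for downstream policy and audit.
    """

    def __init__(self, settings: DecodingSettings) -> None:
        self.settings = settings
        self.calls = 0

    @property
    def cache_tag(self) -> str:
        return self.settings.model_name

    def _post(self, prompt: str) -> str:
        body = json.dumps(
            {
                "model": self.settings.model_name,
                "prompt": prompt,
                "stream": False,
                "options": {
                    "temperature": self.settings.temperature,
                    "top_p": self.settings.top_p,
                    "num_predict": self.settings.max_tokens,
                },
            }
        ).encode()
        req = urllib.request.Request(
            self.settings.endpoint, data=body, headers={"Content-Type": "application/json"}
        )
        with urllib.request.urlopen(req, timeout=self.settings.timeout_seconds) as resp:
            payload = json.loads(resp.read().decode())
        return payload.get("response", "")

    def classify(self, template: PromptTemplate, payload: str) -> ClassifierResponse:
        prompt = assemble_prompt(template, payload)
        last_err: Exception | None = None
        for _ in range(self.settings.retries + 1):
            self.calls += 1
            start = time.monotonic()
            try:
                raw = self._post(prompt)
            except (urllib.error.URLError, OSError, json.JSONDecodeError) as e:
                last_err = e
                continue
            latency = time.monotonic() - start
            return ClassifierResponse(raw, parse_final_answer(raw, template), latency)
        raise BackendError(
            f"model call failed after {self.settings.retries + 1} attempt(s): {last_err}"
        )


@dataclass
class CachedBackend:
    """Disk cache around any backend, keyed by (model tag, prompt hash).

    Cache hits replay the stored raw text and latency without touching
    the inner backend; ``hits``/``misses`` expose call accounting for
    reproducibility checks.
    """

    inner: object
    cache_dir: Path
    hits: int = 0
    misses: int = 0
    _mem: dict = dc_field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.cache_dir = Path(self.cache_dir)
        self.cache_dir.mkdir(parents=True, exist_ok=True)

    @property
    def cache_tag(self):
        return self.inner.cache_tag

    def _key(self, template: PromptTemplate, payload: str) -> str:
        prompt = assemble_prompt(template, payload)
        h = hashlib.sha256(f"{self.inner.cache_tag}\x00{prompt}".encode()).hexdigest()
        return h

    def classify(self, template: PromptTemplate, payload: str) -> ClassifierResponse:
        key = self._key(template, payload)
        path = self.cache_dir / f"{key}.json"
        if key in self._mem or path.exists():
            self.hits += 1
            stored = self._mem.get(key) or json.loads(path.read_text())
            return ClassifierResponse(
                stored["raw_text"],
                parse_final_answer(stored["raw_text"], template),
                stored["latency_seconds"],
            )
        resp = self.inner.classify(template, payload)
        stored = {"raw_text": resp.raw_text, "latency_seconds": resp.latency_seconds}
        path.write_text(json.dumps(stored))
        self._mem[key] = stored
        self.misses += 1
        return resp
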