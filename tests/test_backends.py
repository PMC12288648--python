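"""Prompt assembly, answer parsing, and the oracle/noisy/cached backends."""

import pytest
from hypothesis import given, settings, strategies as st

from respphen.backends import (
    UNPARSEABLE,
    CachedBackend,
    NoisyBackend,
    OracleBackend,
    PromptTemplate,
    TemplateError,
    assemble_prompt,
    default_templates,
    parse_final_answer,
)


@pytest.fixture()
def yn_template():
    return PromptTemplate(
        task="concept-therapy",
        preamble="Review this concept:\n{payload}",
        cot_questions=("Q1: is it a device?", "Q2: which therapy?"),
        final_question="FINAL ANSWER (YES or NO):",
        answer_vocabulary=("YES", "NO"),
    )


def test_assembled_prompt_structure(yn_template):
    payload = "Source = Medication; Concept = LOPRESSOR"
    prompt = assemble_prompt(yn_template, payload)
    assert prompt.count(payload) == 1
    q1, q2 = yn_template.cot_questions
    assert prompt.index(q1) < prompt.index(q2) < prompt.index(yn_template.final_question)
    assert prompt.rstrip().endswith(yn_template.final_question)


def test_empty_cot_gives_preamble_plus_final_question(yn_template):
    t = PromptTemplate(
        task=yn_template.task,
        preamble=yn_template.preamble,
        cot_questions=(),
        final_question=yn_template.final_question,
        answer_vocabulary=yn_template.answer_vocabulary,
    )
    prompt = assemble_prompt(t, "X")
    assert prompt == "Review this concept:\nX\n\nFINAL ANSWER (YES or NO):"


def test_prompt_length_grows_by_payload_length(yn_template):
    short = "X"
    payload = "Source = Medication; Concept = LOPRESSOR"
    grown = len(assemble_prompt(yn_template, payload)) - len(assemble_prompt(yn_template, short))
    assert grown == len(payload) - len(short)


def test_unresolved_placeholder_is_a_template_error():
    t = PromptTemplate(
        task="concept-therapy",
        preamble="{payload} with {definitions}",
        cot_questions=(),
        final_question="FINAL ANSWER (YES or NO):",
        answer_vocabulary=("YES", "NO"),
    )
    with pytest.raises(TemplateError):
        assemble_prompt(t, "X")


@pytest.mark.parametrize(
    ("raw", "expected"),
    [
        ("reasoning...\nFINAL ANSWER (YES or NO): YES", "YES"),
        ("reasoning...\nfinal answer (yes or no): no.", "NO"),
        ("I cannot determine this.", UNPARSEABLE),
        # reasoning mentions both tokens; the last one after the marker wins
        ("maybe YES maybe NO\nFINAL ANSWER (YES or NO): YES, not NO", "NO"),
        ("FINAL ANSWER (YES or NO): nothing\nFINAL ANSWER (YES or NO): YES", "YES"),
    ],
)
def test_parse_final_answer_cases(yn_template, raw, expected):
    assert parse_final_answer(raw, yn_template) == expected


def test_longer_phenotype_tokens_beat_substrings(templates):
    t = templates["phenotype"]
    raw = "thinking about NIPPV...\nFINAL PHENOTYPE: NIPPV Failure"
    assert parse_final_answer(raw, t) == "NIPPV Failure"
    raw2 = "FINAL PHENOTYPE: IMV to HFNI"
    assert parse_final_answer(raw2, t) == "IMV to HFNI"


def test_raw_text_round_trips_for_every_vocabulary_token(templates):
    for template in templates.values():
        for token in template.answer_vocabulary:
            raw = f"Reviewing the input step by step.\n{template.marker} {token}"
            assert parse_final_answer(raw, template) == token


def test_oracle_concept_decisions(lexicon, templates, oracle):
    hi_flow = "Source = Nurse Charting; Concept = O2 Admin Device: Hi Flow NC"
    assert oracle.classify(templates["therapy"], hi_flow).decision == "YES"
    assert oracle.classify(templates["medication"], hi_flow).decision == "NO"
    distractor = "Source = Medication; Concept = LOPRESSOR"
    assert oracle.classify(templates["therapy"], distractor).decision == "NO"
    med = "Source = Infusion Drug; Concept = Propofol (mcg/kg/min)"
    assert oracle.classify(templates["medication"], med).decision == "YES"
    assert all(r.latency_seconds >= 0 for r in [oracle.classify(templates["therapy"], med)])


def test_oracle_phenotypes_description_via_reference_rules(lexicon, templates, oracle):
    desc = "\n".join(
        [
            "1: Source = Nurse Charting; Concept = O2 Admin Device: BiPAP/CPAP",
            "2: Source = Care Plan General; Concept = Ventilation: Non-invasive ventilation",
            "3: Source = Respiratory Care; Concept = Oral ETT",
            "4: Source = Nurse Charting; Concept = O2 Admin Device: Ventilator",
            "5: Source = Medication; Concept = ROCURONIUM 10 MG/ML VIAL",
        ]
    )
    assert oracle.classify(templates["phenotype"], desc).decision == "NIPPV Failure"


def test_noisy_backend_extremes_match_oracle_or_complement(lexicon, templates):
    payloads = sorted(lexicon.relevant_concepts() | lexicon.distractor_concepts)
    oracle = OracleBackend(lexicon)
    frozen = NoisyBackend(lexicon, 0.0, seed=1)
    flipped = NoisyBackend(lexicon, 1.0, seed=1)
    for p in payloads[:30]:
        base = oracle.classify(templates["therapy"], p).decision
        assert frozen.classify(templates["therapy"], p).decision == base
        assert flipped.classify(templates["therapy"], p).decision == ("NO" if base == "YES" else "YES")


def test_noisy_flip_rate_is_near_nominal(lexicon, templates):
    noisy = NoisyBackend(lexicon, 0.25, seed=3)
    oracle = OracleBackend(lexicon)
    payloads = sorted(lexicon.relevant_concepts() | lexicon.distractor_concepts)
    n, flips = 0, 0
    for _ in range(40):
        for p in payloads:
            n += 1
            if noisy.classify(templates["therapy"], p).decision != oracle.classify(
                templates["therapy"], p
            ).decision:
                flips += 1
    assert abs(flips / n - 0.25) < 3 * (0.25 * 0.75 / n) ** 0.5 + 0.01


def test_cache_replays_without_new_calls(tmp_path, lexicon, templates):
    inner = OracleBackend(lexicon)
    cached = CachedBackend(inner, tmp_path)
    payloads = sorted(lexicon.medication_concepts)
    first = [cached.classify(templates["medication"], p).decision for p in payloads]
    assert inner.calls == len(payloads)
    # fresh wrapper over the same directory: zero new inner calls
    inner2 = OracleBackend(lexicon)
    cached2 = CachedBackend(inner2, tmp_path)
    second = [cached2.classify(templates["medication"], p).decision for p in payloads]
    assert second == first
    assert inner2.calls == 0
    assert cached2.hits == len(payloads) and cached2.misses == 0


def test_shipped_templates_load_and_validate(templates):
    assert set(templates) == {"therapy", "medication", "phenotype"}
    assert templates["therapy"].task == "concept-therapy"
    assert templates["phenotype"].answer_vocabulary == (
        "IMV Only", "NIPPV Only", "HFNI Only", "NIPPV Failure",
        "HFNI Failure", "IMV to NIPPV", "IMV to HFNI", "None",
    )
    for t in templates.values():
        assert t.preamble.count("{payload}") == 1


def test_default_decoding_settings_are_greedy():
    from respphen.backends import DecodingSettings

    s = DecodingSettings()
    assert s.temperature == 0.0
    assert s.top_p == 0.99
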