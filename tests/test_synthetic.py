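"""Synthetic cohort generator: determinism, planted criteria, round-trips."""

import numpy as np
import pytest
from scipy import stats

from respphen.concepts import build_concept
from respphen.io import read_tables
from respphen.reference import PHENOTYPES
from respphen.synthetic import (
    GeneratorConfig,
    balanced_concept_sample,
    default_lexicon,
    generate_cohort,
    load_lexicon,
    plant_phenotype,
    save_lexicon,
    write_tables,
)


def test_fixed_seed_reproduces_cohort_exactly():
    cfg = GeneratorConfig(n_patients=60, seed=7)
    out1 = generate_cohort(cfg)
    out2 = generate_cohort(GeneratorConfig(n_patients=60, seed=7))
    assert out1 == out2
    out3 = generate_cohort(GeneratorConfig(n_patients=60, seed=8))
    assert out1[0] != out3[0]


def test_invalid_phenotype_mix_is_a_configuration_error():
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=5, phenotype_mix={"IMV Only": 0.7})
    with pytest.raises(ValueError):
        GeneratorConfig(n_patients=5, phenotype_mix={"Imaginary": 1.0})


def test_lexicon_sets_are_pairwise_disjoint(lexicon):
    sets = [lexicon.therapy_concepts[t] for t in ("IMV", "NIPPV", "HFNI")]
    sets += [lexicon.medication_concepts, lexicon.distractor_concepts]
    assert sum(len(s) for s in sets) == len(set().union(*sets))


def test_planted_imv_only_meets_record_criteria(lexicon, rng):
    for _ in range(20):
        records, offsets = plant_phenotype("IMV Only", lexicon, rng)
        texts = [build_concept(r).text for r in records]
        assert sum(t in lexicon.therapy_concepts["IMV"] for t in texts) >= 2
        assert sum(t in lexicon.medication_concepts for t in texts) >= 1
        noninv = lexicon.therapy_concepts["NIPPV"] | lexicon.therapy_concepts["HFNI"]
        assert not any(t in noninv for t in texts)


def test_planted_hfni_only_has_hfni_evidence(lexicon, rng):
    for _ in range(20):
        records, _ = plant_phenotype("HFNI Only", lexicon, rng)
        texts = [build_concept(r).text for r in records]
        noninv = [t for t in texts if t in lexicon.therapy_concepts["NIPPV"]
                  or t in lexicon.therapy_concepts["HFNI"]]
        assert len(noninv) >= 2
        assert any(t in lexicon.therapy_concepts["HFNI"] for t in noninv)


def test_planted_failure_sequences_are_strictly_ordered(lexicon, rng):
    for phenotype, first in (("NIPPV Failure", "NIPPV"), ("HFNI Failure", "HFNI")):
        for _ in range(20):
            _, offsets = plant_phenotype(phenotype, lexicon, rng)
            assert max(offsets[first]) < min(offsets["IMV"])
    for phenotype, second in (("IMV to NIPPV", "NIPPV"), ("IMV to HFNI", "HFNI")):
        for _ in range(20):
            _, offsets = plant_phenotype(phenotype, lexicon, rng)
            assert max(offsets["IMV"]) < min(offsets[second])


def test_planted_none_never_satisfies_a_therapy(lexicon, rng):
    from respphen.reference import phenotype_encounter

    for _ in range(40):
        records, _ = plant_phenotype("None", lexicon, rng)
        assert phenotype_encounter(records, lexicon) == "None"


def test_unknown_phenotype_rejected(lexicon, rng):
    with pytest.raises(ValueError):
        plant_phenotype("IMV then nothing", lexicon, rng)


def test_cohort_includes_filterable_encounters(small_cohort):
    _, encounters, truths = small_cohort
    assert any(e.admit_order > 1 for e in encounters)
    excluded = {t.encounter_id for t in truths if not t.included}
    assert excluded  # repeat or under-18 encounters exist and are flagged


def test_phenotype_mix_converges(lexicon):
    # balanced 4-class mix so expected counts are large enough for chi-square
    mix = {"IMV Only": 0.25, "NIPPV Only": 0.25, "HFNI Only": 0.25, "None": 0.25}
    cfg = GeneratorConfig(n_patients=5000, phenotype_mix=mix, distractor_rate=0.0,
                          extra_encounter_rate=0.0, seed=11)
    _, _, truths = generate_cohort(cfg)
    counts = {p: 0 for p in mix}
    for t in truths:
        counts[t.phenotype] += 1
    n = sum(counts.values())
    expected = [mix[p] * n for p in mix]
    chi2, p_value = stats.chisquare([counts[p] for p in mix], expected)
    assert p_value > 0.001


def test_write_read_round_trip(tmp_path, small_cohort):
    records, encounters, truths = small_cohort
    write_tables(records, encounters, tmp_path, truths)
    back_records, back_encounters = read_tables(tmp_path)
    key = lambda r: (r.encounter_id, r.table, r.offset_minutes, r.fields)
    assert sorted(back_records, key=key) == sorted(records, key=key)
    assert sorted(back_encounters, key=lambda e: e.encounter_id) == sorted(
        encounters, key=lambda e: e.encounter_id
    )


def test_empty_cohort_writes_headers_only(tmp_path):
    paths = write_tables([], [], tmp_path)
    csvs = [p for p in paths if p.suffix == ".csv"]
    assert len(csvs) == 10  # 9 tables + patient.csv
    for p in csvs:
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and "," in lines[0]


def test_lexicon_yaml_round_trip(tmp_path, lexicon):
    path = tmp_path / "lexicon.yaml"
    save_lexicon(lexicon, path)
    assert load_lexicon(path) == lexicon


def test_balanced_concept_sample_is_balanced_and_consistent():
    lex, texts, truth = balanced_concept_sample(400, seed=5)
    assert len(texts) == 400 and len(set(texts)) == 400
    assert sum(truth.values()) == 200
    relevant = lex.relevant_concepts()
    for t in texts:
        assert truth[t] == (t in relevant)
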