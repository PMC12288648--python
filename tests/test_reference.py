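"""Rule-based reference phenotyper: therapy criteria, interval rule, filters."""

import pytest
from hypothesis import given, settings, strategies as st

from respphen.reference import (
    AmbiguityError,
    Encounter,
    TherapyEpisode,
    UnclassifiableError,
    apply_imv_interval_rule,
    classify_phenotype,
    detect_therapies,
    filter_adults,
    parse_age,
    phenotype_encounter,
    select_first_encounters,
)

IMV1 = "Source = Respiratory Care; Concept = Oral ETT"
IMV2 = "Source = Nurse Charting; Concept = O2 Admin Device: Ventilator"
MED = "Source = Medication; Concept = ROCURONIUM 10 MG/ML VIAL"
NIPPV1 = "Source = Nurse Charting; Concept = O2 Admin Device: BiPAP/CPAP"
NIPPV2 = "Source = Care Plan General; Concept = Ventilation: Non-invasive ventilation"
HFNI1 = "Source = Nurse Charting; Concept = O2 Admin Device: Hi Flow NC"
DISTRACTOR = "Source = Medication; Concept = LOPRESSOR"


# --- cohort filters


def test_first_encounter_kept_per_patient():
    encs = [
        Encounter("E1", "P1", "45", 2),
        Encounter("E2", "P1", "45", 1),
        Encounter("E3", "P1", "45", 3),
        Encounter("E4", "P2", "60", 1),
    ]
    kept = select_first_encounters(encs)
    assert {e.encounter_id for e in kept} == {"E2", "E4"}
    assert len(kept) == len({e.patient_id for e in encs})


def test_duplicate_admit_order_is_ambiguous():
    encs = [Encounter("E1", "P1", "45", 1), Encounter("E2", "P1", "45", 1)]
    with pytest.raises(AmbiguityError):
        select_first_encounters(encs)


@pytest.mark.parametrize(
    ("age", "included"),
    [("17", False), ("18", True), ("45", True), (">89", True), ("not-a-number", False)],
)
def test_adult_filter_boundaries(age, included):
    encs = [Encounter("E1", "P1", age, 1)]
    assert bool(filter_adults(encs)) is included


def test_elder_sentinel_parses_as_90():
    assert parse_age(">89") == 90
    assert parse_age("89") == 89
    assert parse_age("??") is None


# --- therapy detection


def test_imv_needs_two_records_and_a_medication(lexicon, make_records):
    recs = make_records([(IMV1, 10), (IMV2, 50), (MED, 5)])
    episodes = detect_therapies(recs, lexicon)
    assert [e.therapy for e in episodes] == ["IMV"]
    assert (episodes[0].start_offset, episodes[0].end_offset) == (10, 50)

    no_med = make_records([(IMV1, 10), (IMV2, 50)])
    assert detect_therapies(no_med, lexicon) == []


def test_two_nippv_records_without_hfni_is_nippv(lexicon, make_records):
    recs = make_records([(NIPPV1, 10), (NIPPV2, 20)])
    episodes = detect_therapies(recs, lexicon)
    assert [e.therapy for e in episodes] == ["NIPPV"]


def test_one_nippv_plus_one_hfni_is_hfni(lexicon, make_records):
    recs = make_records([(NIPPV1, 10), (HFNI1, 20)])
    episodes = detect_therapies(recs, lexicon)
    assert [e.therapy for e in episodes] == ["HFNI"]


def test_single_therapy_record_detects_nothing(lexicon, make_records):
    assert detect_therapies(make_records([(NIPPV1, 10)]), lexicon) == []


def test_imv_counts_records_not_distinct_concepts(lexicon, make_records):
    # the same IMV concept charted twice still counts as two records
    recs = make_records([(IMV1, 10), (IMV1, 200), (MED, 5)])
    assert [e.therapy for e in detect_therapies(recs, lexicon)] == ["IMV"]


# --- interval rule


def test_noninvasive_records_inside_imv_span_are_removed(lexicon, make_records):
    recs = make_records([(IMV1, 50), (IMV2, 300), (MED, 5), (NIPPV1, 100), (NIPPV2, 200)])
    assert phenotype_encounter(recs, lexicon) == "IMV Only"


def test_noninvasive_records_outside_imv_span_are_retained(lexicon, make_records):
    recs = make_records([(IMV1, 50), (IMV2, 300), (MED, 5), (NIPPV1, 10), (NIPPV2, 20)])
    assert phenotype_encounter(recs, lexicon) == "NIPPV Failure"


def test_interval_rule_identity_without_imv(lexicon, make_records):
    recs = make_records([(NIPPV1, 10), (NIPPV2, 20)])
    assert apply_imv_interval_rule(recs, None, lexicon) == list(recs)


def test_interval_rule_closed_boundaries_and_idempotence(lexicon, make_records):
    recs = make_records([(IMV1, 100), (IMV2, 300), (MED, 5), (NIPPV1, 100), (NIPPV2, 300)])
    imv = detect_therapies(recs, lexicon)[0]
    once = apply_imv_interval_rule(recs, imv, lexicon)
    # boundary offsets are inside the closed interval
    assert {r.offset_minutes for r in once} == {100, 300, 5}
    assert all("BiPAP" not in str(r.fields) for r in once)
    assert apply_imv_interval_rule(once, imv, lexicon) == once


# --- classification


def test_classification_orderings():
    nippv = TherapyEpisode("NIPPV", 10, 40, 2)
    hfni = TherapyEpisode("HFNI", 900, 950, 2)
    imv = TherapyEpisode("IMV", 500, 600, 2)
    assert classify_phenotype([]) == "None"
    assert classify_phenotype([imv]) == "IMV Only"
    assert classify_phenotype([nippv]) == "NIPPV Only"
    assert classify_phenotype([nippv, imv]) == "NIPPV Failure"
    assert classify_phenotype([TherapyEpisode("HFNI", 10, 40, 2), imv]) == "HFNI Failure"
    assert classify_phenotype([TherapyEpisode("IMV", 10, 60, 2), hfni]) == "IMV to HFNI"
    assert classify_phenotype([TherapyEpisode("IMV", 10, 60, 2),
                               TherapyEpisode("NIPPV", 900, 950, 2)]) == "IMV to NIPPV"


def test_start_offset_tie_is_surfaced_not_coerced():
    with pytest.raises(UnclassifiableError):
        classify_phenotype([TherapyEpisode("IMV", 10, 60, 2), TherapyEpisode("NIPPV", 10, 90, 2)])


def test_two_noninvasive_episodes_are_unclassifiable():
    with pytest.raises(UnclassifiableError):
        classify_phenotype([TherapyEpisode("NIPPV", 10, 60, 2), TherapyEpisode("HFNI", 70, 90, 2)])


# --- full per-encounter pipeline properties


def test_distractor_only_encounter_is_none(lexicon, make_records):
    recs = make_records([(DISTRACTOR, 10), (DISTRACTOR, 400)])
    assert phenotype_encounter(recs, lexicon) == "None"


@settings(deadline=None, max_examples=30)
@given(st.randoms(use_true_random=False))
def test_label_is_permutation_invariant(lexicon, make_records, rnd):
    recs = make_records(
        [(NIPPV1, 10), (NIPPV2, 20), (IMV1, 500), (IMV2, 600), (MED, 550), (DISTRACTOR, 5)]
    )
    shuffled = list(recs)
    rnd.shuffle(shuffled)
    assert phenotype_encounter(shuffled, lexicon) == phenotype_encounter(recs, lexicon)


def test_adding_distractors_never_changes_label(lexicon, make_records, small_cohort):
    records, _, truths = small_cohort
    by_enc = {}
    for r in records:
        by_enc.setdefault(r.encounter_id, []).append(r)
    extra = make_records([(DISTRACTOR, off) for off in (0, 123, 4999)], encounter_id="ignored")
    for t in truths[:40]:
        recs = by_enc.get(t.encounter_id, [])
        base = phenotype_encounter(recs, lexicon)
        assert phenotype_encounter(recs + extra, lexicon) == base


def test_reference_recovers_every_planted_label(lexicon, small_cohort):
    records, _, truths = small_cohort
    by_enc = {}
    for r in records:
        by_enc.setdefault(r.encounter_id, []).append(r)
    for t in truths:
        assert phenotype_encounter(by_enc.get(t.encounter_id, []), lexicon) == t.phenotype
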