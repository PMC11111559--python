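import datetime as dt
import random

import pytest

from fnepisodes.config import PipelineConfig
from fnepisodes.datamodel import ClaimsDataset, EnrollmentSpan
from fnepisodes.episode_builder import (apply_washout, build_cohort,
                                        detect_candidates, qualify,
                                        terminate_episode, washout_gap_ok)

from conftest import D, dataset, fn_index_claims, med, member, qualifying_member_claims, rx
from reference import naive_cohort

DAYS = dt.timedelta


# --- candidate detection ---------------------------------------------------

def test_inpatient_claim_with_neutropenia_and_fever_is_candidate(codesets):
    m, _ = fn_index_claims("M1", D(2016, 6, 1))
    cands = detect_candidates(dataset(medical=m), codesets)
    assert [(c.member_id, c.index_date, c.trigger) for c in cands] == [
        ("M1", D(2016, 6, 1), "inpatient_def")]


def test_outpatient_dx_without_antibiotic_is_not_candidate(codesets):
    claims = [med("M1", D(2016, 6, 1), "physician_office", dx=["D70.9", "A41.9"])]
    assert detect_candidates(dataset(medical=claims), codesets) == []


def test_outpatient_definition_requires_configured_oral_combination(codesets):
    day = D(2016, 6, 1)
    base = [med("M1", day, "physician_office", dx=["D70.9", "A41.9"])]
    # ciprofloxacin alone is not an accepted oral regimen
    only_cipro = dataset(medical=base, pharmacy=[rx("M1", day, "CIP500")])
    assert detect_candidates(only_cipro, codesets) == []
    # ciprofloxacin + amoxicillin/clavulanate is
    combo = dataset(medical=base, pharmacy=[rx("M1", day, "CIP500"),
                                            rx("M1", day, "AMC875")])
    cands = detect_candidates(combo, codesets)
    assert len(cands) == 1 and cands[0].trigger == "outpatient_def"


def test_parenteral_antibiotic_procedure_satisfies_outpatient_definition(codesets):
    day = D(2016, 6, 1)
    claims = [med("M1", day, "emergency_room", dx=["D70.9", "R50.9"], proc=["J0696"])]
    cands = detect_candidates(dataset(medical=claims), codesets)
    assert len(cands) == 1 and cands[0].trigger == "outpatient_def"


def test_same_date_dx_may_span_claims_unless_strict(codesets):
    day = D(2016, 6, 1)
    claims = [
        med("M1", day, "inpatient", dx=["D70.9"], discharge=day + DAYS(2)),
        med("M1", day, "inpatient", dx=["R50.9"], discharge=day + DAYS(2)),
    ]
    ds = dataset(medical=claims)
    assert len(detect_candidates(ds, codesets)) == 1
    strict = PipelineConfig(require_same_claim_dx=True)
    assert detect_candidates(ds, codesets, strict) == []


def test_hand_built_fixture_matches_exhaustive_enumeration(codesets):
    """12 claims exercising both definitions and both failure modes; the
    candidate set must equal a brute-force scan of every (member, date)."""
    d0 = D(2017, 3, 1)
    medical = [
        # member A: inpatient definition fires on d0
        med("A", d0, "inpatient", dx=["D70.9", "B37.0"], discharge=d0 + DAYS(4)),
        # member A: neutropenia alone later -> no candidate
        med("A", d0 + DAYS(40), "inpatient", dx=["D70.9"], discharge=d0 + DAYS(42)),
        # member B: outpatient definition with oral combo
        med("B", d0, "physician_office", dx=["D70.1", "R50.9"]),
        # member B: same dx next day but no antibiotic -> no candidate
        med("B", d0 + DAYS(1), "physician_office", dx=["D70.1", "R50.9"]),
        # member C: fever alone -> never a candidate
        med("C", d0, "inpatient", dx=["R50.9"], discharge=d0 + DAYS(1)),
        # member C: infection + neutropenia but outpatient, parenteral abx
        med("C", d0 + DAYS(10), "other_outpatient", dx=["D70.8", "J15.9"], proc=["J2543"]),
        # member D: both definitions same day -> recorded once as inpatient
        med("D", d0, "inpatient", dx=["D70.9", "R50.81"], discharge=d0 + DAYS(3)),
        med("D", d0, "emergency_room", dx=["D70.9", "R50.81"]),
    ]
    pharmacy = [
        rx("B", d0, "CIP250"), rx("B", d0, "CLD300"),
        rx("D", d0, "LVX750"),
        rx("C", d0, "CIP250"),  # cipro alone on a fever-only day
    ]
    ds = dataset(medical=medical, pharmacy=pharmacy)
    got = {(c.member_id, c.index_date, c.trigger) for c in detect_candidates(ds, codesets)}
    assert got == {
        ("A", d0, "inpatient_def"),
        ("B", d0, "outpatient_def"),
        ("C", d0 + DAYS(10), "outpatient_def"),
        ("D", d0, "inpatient_def"),
    }


# --- qualification ---------------------------------------------------------

def _qualify_ds(chemo_offset, codesets, **kwargs):
    index = D(2016, 6, 1)
    m, p = fn_index_claims("M1", index)
    m.append(med("M1", index - DAYS(chemo_offset), proc=["J9201"]))
    ds = dataset(medical=m, pharmacy=p, **kwargs)
    (cand,) = detect_candidates(ds, codesets)
    return cand, ds


def test_chemo_at_minus_30_qualifies_minus_31_does_not(codesets):
    cand, ds = _qualify_ds(30, codesets)
    assert qualify(cand, ds, codesets) is None
    cand, ds = _qualify_ds(31, codesets)
    rej = qualify(cand, ds, codesets)
    assert rej is not None and rej.reason == "chemo_within_window"


def test_fever_dx_day_before_index_disqualifies_but_index_day_does_not(codesets):
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index)
    m.append(med("M1", index - DAYS(1), dx=["R50.9"]))
    (cand,) = detect_candidates(dataset(medical=m, pharmacy=p), codesets)
    rej = qualify(cand, dataset(medical=m, pharmacy=p), codesets)
    assert rej is not None and rej.reason == "clean_pre_period"

    # the index-date FN dx itself never disqualifies
    m2, p2 = qualifying_member_claims("M2", index)
    (cand2,) = detect_candidates(dataset(medical=m2, pharmacy=p2), codesets)
    assert qualify(cand2, dataset(medical=m2, pharmacy=p2), codesets) is None


def test_enrollment_gap_in_pre_period_disqualifies(codesets):
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index)
    spans = [EnrollmentSpan("M1", index - DAYS(150), index + DAYS(90))]
    ds = dataset(medical=m, pharmacy=p, enrollment=spans)
    (cand,) = detect_candidates(ds, codesets)
    rej = qualify(cand, ds, codesets)
    assert rej is not None and rej.reason == "continuous_enrollment"


@pytest.mark.parametrize(
    "extra_claim, reason",
    [
        (lambda i: med("M1", i - DAYS(90), proc=["38240"]), "no_bmt_sct_cart"),
        (lambda i: med("M1", i - DAYS(100), dx=["C92.00"]), "no_excluded_heme_malignancy"),
        (lambda i: med("M1", i - DAYS(20), dx=["U07.1"]), "no_covid19"),
        (lambda i: med("M1", i, dx=["U07.1"]), "no_covid19"),  # on index date
    ],
)
def test_exclusion_criteria_fire_with_their_labels(codesets, extra_claim, reason):
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index)
    m.append(extra_claim(index))
    ds = dataset(medical=m, pharmacy=p)
    (cand,) = detect_candidates(ds, codesets)
    rej = qualify(cand, ds, codesets)
    assert rej is not None and rej.reason == reason


# --- termination -----------------------------------------------------------

def test_no_chemo_no_hospitalization_caps_at_60_days_length_61(codesets):
    index = D(2016, 6, 1)
    m, p = fn_index_claims("M1", index, inpatient=False)
    m.append(med("M1", index - DAYS(10), proc=["J9201"]))
    ds = dataset(medical=m, pharmacy=p)
    (cand,) = detect_candidates(ds, codesets)
    end, hosp = terminate_episode(cand, ds, codesets)
    assert end == index + DAYS(60) and not hosp
    assert (end - index).days + 1 == 61


def test_next_chemo_terminates_episode(codesets):
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index, inpatient=False)
    m.append(med("M1", index + DAYS(20), proc=["J9201"]))
    ds = dataset(medical=m, pharmacy=p)
    (cand,) = detect_candidates(ds, codesets)
    end, _ = terminate_episode(cand, ds, codesets)
    assert end == index + DAYS(20)


def test_chemo_on_index_date_does_not_terminate(codesets):
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index, inpatient=False)
    m.append(med("M1", index, proc=["J9201"]))
    ds = dataset(medical=m, pharmacy=p)
    (cand,) = detect_candidates(ds, codesets)
    end, _ = terminate_episode(cand, ds, codesets)
    assert end == index + DAYS(60)


def test_fn_hospitalization_extends_past_cap(codesets):
    """An FN stay admitted day 55 and discharged day 70 extends the episode
    to day 70 — lengths beyond the 60-day cap arise only this way."""
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index, inpatient=False)
    m.append(med("M1", index + DAYS(55), "inpatient", dx=["R50.9"],
                 discharge=index + DAYS(70)))
    ds = dataset(medical=m, pharmacy=p)
    (cand,) = detect_candidates(ds, codesets)
    end, hosp = terminate_episode(cand, ds, codesets)
    assert end == index + DAYS(70) and hosp
    assert (end - index).days + 1 == 71  # exceeds 61 only via extension


def test_non_fn_hospitalization_does_not_extend(codesets):
    index = D(2016, 6, 1)
    m, p = qualifying_member_claims("M1", index, inpatient=False)
    m.append(med("M1", index + DAYS(55), "inpatient", dx=["Z00.00"],
                 discharge=index + DAYS(70)))
    ds = dataset(medical=m, pharmacy=p)
    (cand,) = detect_candidates(ds, codesets)
    end, hosp = terminate_episode(cand, ds, codesets)
    assert end == index + DAYS(60) and hosp


# --- washout ---------------------------------------------------------------

def test_washout_gap_brute_force_equivalence():
    """washout_gap_ok must agree with scanning every 30-day window."""
    rng = random.Random(17)
    base = D(2016, 1, 1)
    for _ in range(200):
        prior_end = base + DAYS(rng.randrange(0, 30))
        index = prior_end + DAYS(rng.randrange(1, 120))
        fn_days = sorted({prior_end + DAYS(rng.randrange(1, max((index - prior_end).days, 2)))
                          for _ in range(rng.randrange(0, 6))})
        naive = any(
            all((start + DAYS(k)) not in fn_days for k in range(30))
            for start in (prior_end + DAYS(s + 1)
                          for s in range((index - prior_end).days - 30))
        )
        assert washout_gap_ok(prior_end, index, fn_days, 30) == naive


def test_second_candidate_10_days_after_end_is_dropped(codesets):
    index1 = D(2016, 3, 1)
    m, p = qualifying_member_claims("M1", index1, inpatient=False)
    m.append(med("M1", index1 + DAYS(20), proc=["J9201"]))  # ends episode 1
    index2 = index1 + DAYS(30)  # 10 days after end
    m2, p2 = fn_index_claims("M1", index2, inpatient=False)
    ds = dataset(medical=m + m2, pharmacy=p + p2)
    episodes, _ = build_cohort(ds, codesets)
    assert [e.index_date for e in episodes] == [index1]


def test_second_candidate_after_clean_gap_is_retained(codesets):
    index1 = D(2016, 3, 1)
    m, p = qualifying_member_claims("M1", index1, inpatient=False)
    m.append(med("M1", index1 + DAYS(20), proc=["J9201"]))
    index2 = index1 + DAYS(60)  # 39 clean days after end
    m2, p2 = fn_index_claims("M1", index2, inpatient=False)
    m2.append(med("M1", index2 - DAYS(5), proc=["J9201"]))
    ds = dataset(medical=m + m2, pharmacy=p + p2)
    episodes, _ = build_cohort(ds, codesets)
    assert [e.index_date for e in episodes] == [index1, index2]
    # under the strict full-clean-period reading the second one is rejected
    strict = PipelineConfig(subsequent_episode_rule="full_clean_period")
    episodes2, _ = build_cohort(ds, codesets, strict)
    assert [e.index_date for e in episodes2] == [index1]


def test_apply_washout_retains_first_and_gapped_episodes(codesets):
    from fnepisodes.episode_builder import FNEpisode

    m = [med("M1", D(2016, 5, 1), dx=["R50.9"])]  # fever inside the gap
    ds = dataset(medical=m)
    eps = [
        FNEpisode("e1", "M1", D(2016, 3, 1), D(2016, 4, 1), False, "inpatient_def"),
        FNEpisode("e2", "M1", D(2016, 5, 20), D(2016, 6, 1), False, "inpatient_def"),
        FNEpisode("e3", "M1", D(2016, 8, 1), D(2016, 9, 1), False, "inpatient_def"),
    ]
    retained = apply_washout(eps, ds, codesets)
    assert [e.episode_id for e in retained] == ["e1", "e3"]


# --- whole-pipeline properties --------------------------------------------

def test_empty_dataset_gives_zero_episodes_and_zero_log(codesets):
    ds = dataset(members=[member("M1")])
    episodes, log = build_cohort(ds, codesets)
    assert episodes == []
    assert all(n == 0 for _, n in log.steps)


def test_retained_episode_intervals_are_disjoint_per_member(codesets):
    from fnepisodes.synthetic_claims import GeneratorConfig, generate_synthetic_claims

    ds, _ = generate_synthetic_claims(GeneratorConfig(n_members=60, seed=11,
                                                      p_second_episode=0.5))
    episodes, log = build_cohort(ds, codesets)
    log.validate()
    by_member = {}
    for e in episodes:
        by_member.setdefault(e.member_id, []).append(e)
    for eps in by_member.values():
        eps.sort(key=lambda e: e.index_date)
        for a, b in zip(eps, eps[1:]):
            assert a.end_date < b.index_date


def test_claim_order_does_not_change_episode_set(codesets):
    ds, _ = _random_small_dataset(seed=3)
    episodes, _ = build_cohort(ds, codesets)
    key = {(e.member_id, e.index_date, e.end_date, e.has_hospitalization) for e in episodes}
    rng = random.Random(5)
    for _ in range(3):
        medical = list(ds.medical)
        pharmacy = list(ds.pharmacy)
        rng.shuffle(medical)
        rng.shuffle(pharmacy)
        shuffled = ClaimsDataset(members=ds.members, enrollment=list(ds.enrollment),
                                 medical=medical, pharmacy=pharmacy)
        episodes2, _ = build_cohort(shuffled, codesets)
        assert {(e.member_id, e.index_date, e.end_date, e.has_hospitalization)
                for e in episodes2} == key


def test_adding_pre_period_fever_claim_only_removes_episodes(codesets):
    index = D(2016, 6, 1)
    claims, p = qualifying_member_claims("M1", index)
    ds = dataset(medical=claims, pharmacy=p)
    n_before = len(build_cohort(ds, codesets)[0])
    ds2 = dataset(medical=claims + [med("M1", index - DAYS(90), dx=["R50.9"])],
                  pharmacy=p)
    n_after = len(build_cohort(ds2, codesets)[0])
    assert n_before == 1 and n_after == 0


# --- oracle equivalence on random small datasets ---------------------------

FN_DX = ["D70.9", "R50.9", "A41.9", "B37.0"]
OTHER_DX = ["Z00.00", "E11.9", "C50.911", "U07.1", "C92.00"]
PROCS = ["J9201", "J9045", "38240", "J0696", "19303"]
DRUGS = ["LVX500", "CIP500", "AMC875", "J2505", "OTH001"]


def _random_small_dataset(seed):
    """<=6 members, dense random claims over ~10 months."""
    rng = random.Random(seed)
    base = D(2017, 1, 1)
    medical, pharmacy, enrollment = [], [], []
    n_members = rng.randrange(2, 7)
    for i in range(n_members):
        mid = f"R{i}"
        # enrollment: one or two spans
        s = base + DAYS(rng.randrange(0, 60))
        e = s + DAYS(rng.randrange(200, 500))
        enrollment.append(EnrollmentSpan(mid, s, e))
        if rng.random() < 0.3:
            s2 = e + DAYS(rng.randrange(1, 40))
            enrollment.append(EnrollmentSpan(mid, s2, s2 + DAYS(rng.randrange(60, 200))))
        for _ in range(rng.randrange(5, 25)):
            day = base + DAYS(rng.randrange(0, 300))
            setting = rng.choice(["inpatient", "emergency_room", "physician_office",
                                  "other_outpatient"])
            dx = rng.sample(FN_DX, k=rng.randrange(0, 3)) + rng.sample(
                OTHER_DX, k=rng.randrange(0, 2))
            proc = rng.sample(PROCS, k=rng.randrange(0, 2))
            discharge = day + DAYS(rng.randrange(0, 20)) if setting == "inpatient" else None
            medical.append(med(mid, day, setting, dx=dx, proc=proc, discharge=discharge))
        for _ in range(rng.randrange(0, 8)):
            day = base + DAYS(rng.randrange(0, 300))
            pharmacy.append(rx(mid, day, rng.choice(DRUGS)))
    return dataset(medical=medical, pharmacy=pharmacy, enrollment=enrollment), None


@pytest.mark.parametrize("seed", range(15))
def test_build_cohort_matches_naive_reference(codesets, seed):
    """On small random datasets the pipeline must equal a day-by-day
    exhaustive reference implementation of every rule."""
    ds, _ = _random_small_dataset(seed)
    config = PipelineConfig()
    episodes, _ = build_cohort(ds, codesets, config)
    got = [(e.member_id, e.index_date, e.end_date, e.has_hospitalization)
           for e in episodes]
    assert got == naive_cohort(ds, codesets, config)
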