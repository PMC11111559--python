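"""Deliberately naive reference implementation of episode construction.

Used only as an independent oracle on tiny datasets: every rule is
evaluated by brute force — scanning each (member, date) pair and every
day of every window — with no indexing, merging, or short-cuts shared
with the production implementation.
"""

from __future__ import annotations

import datetime as dt

ONE = dt.timedelta(days=1)


def _days(lo, hi):
    d = lo
    while d <= hi:
        yield d
        d += ONE


def _med_on(dataset, member_id, day):
    return [c for c in dataset.medical if c.member_id == member_id and c.service_date == day]


def _rx_on(dataset, member_id, day):
    return [c for c in dataset.pharmacy if c.member_id == member_id and c.fill_date == day]


def _has_dx(claims, codes):
    return any(d in codes for c in claims for d in c.dx_codes)


def _has_proc(claims, codes):
    return any(p in codes for c in claims for p in c.proc_codes)


def _is_chemo_day(dataset, member_id, day, codesets):
    return _has_proc(_med_on(dataset, member_id, day), codesets.chemo_codes) or any(
        c.drug_code in codesets.chemo_codes for c in _rx_on(dataset, member_id, day)
    )


def _is_fn_dx_day(dataset, member_id, day, codesets):
    return _has_dx(_med_on(dataset, member_id, day), codesets.fn_dx)


def _candidate_on(dataset, member_id, day, codesets, config):
    med = _med_on(dataset, member_id, day)
    neut = codesets["neutropenia_dx"]
    inf = codesets.infection_fever_dx

    def dx_met(claims):
        if config.require_same_claim_dx:
            return any(_has_dx([c], neut) and _has_dx([c], inf) for c in claims)
        return _has_dx(claims, neut) and _has_dx(claims, inf)

    inpatient = [c for c in med if c.setting == "inpatient"]
    if dx_met(inpatient):
        return "inpatient_def"
    outpatient = [c for c in med if c.setting != "inpatient"]
    if dx_met(outpatient):
        drugs = {c.drug_code for c in _rx_on(dataset, member_id, day)}
        oral = any(
            all(drugs & codesets[name] for name in combo)
            for combo in codesets.oral_antibiotic_combinations
        )
        if oral or _has_proc(med, codesets["nccn_parenteral_antibiotic_proc"]):
            return "outpatient_def"
    return None


def _enrolled_every_day(dataset, member_id, lo, hi):
    for day in _days(lo, hi):
        if not any(s.member_id == member_id and s.start_date <= day <= s.end_date
                   for s in dataset.enrollment):
            return False
    return True


def _first_rejection(dataset, member_id, index, codesets, config, subsequent):
    pre_lo = index - dt.timedelta(days=config.pre_window_days)
    pre_hi = index - ONE

    chemo_hi = index if config.chemo_window_includes_index else pre_hi
    if not any(_is_chemo_day(dataset, member_id, d, codesets)
               for d in _days(index - dt.timedelta(days=config.chemo_window_days), chemo_hi)):
        return "chemo_within_window"
    if not _enrolled_every_day(dataset, member_id, pre_lo, index):
        return "continuous_enrollment"
    skip = subsequent and config.subsequent_episode_rule == "washout_gap"
    if not skip and any(_is_fn_dx_day(dataset, member_id, d, codesets)
                        for d in _days(pre_lo, pre_hi)):
        return "clean_pre_period"
    if any(_has_proc(_med_on(dataset, member_id, d), codesets["bmt_sct_cart_proc"])
           for d in _days(pre_lo, pre_hi)):
        return "no_bmt_sct_cart"
    if any(_has_dx(_med_on(dataset, member_id, d), codesets["excluded_heme_dx"])
           for d in _days(pre_lo, pre_hi)):
        return "no_excluded_heme_malignancy"
    covid_hi = index if config.covid_exclusion_includes_index else pre_hi
    if any(_has_dx(_med_on(dataset, member_id, d), codesets["covid_dx"])
           for d in _days(pre_lo, covid_hi)):
        return "no_covid19"
    return None


def _terminate(dataset, member_id, index, codesets, config):
    cap = index + dt.timedelta(days=config.episode_cap_days)
    provisional = cap
    for day in _days(index + ONE, cap):
        if _is_chemo_day(dataset, member_id, day, codesets):
            provisional = day
            break
    end = provisional
    for day in _days(index, provisional):
        for c in _med_on(dataset, member_id, day):
            if (c.setting == "inpatient" and c.discharge_date is not None
                    and any(d in codesets.fn_dx for d in c.dx_codes)
                    and c.discharge_date > end):
                end = c.discharge_date
    hosp = any(
        any(c.setting == "inpatient" for c in _med_on(dataset, member_id, day))
        for day in _days(index, end)
    )
    return end, hosp


def _clean_gap_exists(dataset, member_id, prior_end, index, codesets, config):
    w = config.washout_days
    start = prior_end + ONE
    while start + dt.timedelta(days=w - 1) <= index - ONE:
        if all(not _is_fn_dx_day(dataset, member_id, d, codesets)
               for d in _days(start, start + dt.timedelta(days=w - 1))):
            return True
        start += ONE
    return False


def naive_cohort(dataset, codesets, config):
    """Episode list [(member_id, index, end, has_hosp)] by exhaustive scan."""
    episodes = []
    member_ids = sorted({c.member_id for c in dataset.medical}
                        | {c.member_id for c in dataset.pharmacy})
    for member_id in member_ids:
        days = sorted({c.service_date for c in dataset.medical if c.member_id == member_id})
        prior_end = None
        for day in days:
            if _candidate_on(dataset, member_id, day, codesets, config) is None:
                continue
            if _first_rejection(dataset, member_id, day, codesets, config,
                                subsequent=prior_end is not None) is not None:
                continue
            if prior_end is not None and not _clean_gap_exists(
                    dataset, member_id, prior_end, day, codesets, config):
                continue
            end, hosp = _terminate(dataset, member_id, day, codesets, config)
            episodes.append((member_id, day, end, hosp))
            prior_end = end
    return episodes
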