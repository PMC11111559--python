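"""Episode construction: candidate detection, qualification, termination,
and inter-episode washout, with full attrition logging.

The case definition has two arms.  An inpatient candidate is a date on
which a member's inpatient claims carry a neutropenia diagnosis together
with a fever, bacterial-infection, or fungal-infection diagnosis.  An
outpatient candidate additionally requires same-date evidence of an
NCCN-recommended antibiotic: an oral regimen from the configured
combination rules filled that day, or a parenteral-antibiotic procedure
code.  The index date anchors a 180-day pre-episode window and a 30-day
chemotherapy treatment window; qualification, termination (next incident
chemotherapy or the 60-day cap, extended through an FN-related inpatient
stay that runs past the provisional end), and the 30-day washout then
produce the final episode set.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel import ClaimsDataset, CodeSets, Date, MedicalClaim

ONE_DAY = dt.timedelta(days=1)

#: fixed evaluation order of the qualification criteria; rejections carry
#: the first failing label and the attrition log counts survivors in this
#: order.
CRITERIA = (
    "chemo_within_window",
    "continuous_enrollment",
    "clean_pre_period",
    "no_bmt_sct_cart",
    "no_excluded_heme_malignancy",
    "no_covid19",
)


@dataclass(frozen=True)
class CandidateIndexEvent:
    member_id: str
    index_date: Date
    trigger: str  # "inpatient_def" | "outpatient_def"
    triggering_claim_ids: tuple[str, ...]


@dataclass(frozen=True)
class Rejection:
    candidate: CandidateIndexEvent
    reason: str


@dataclass(frozen=True)
class FNEpisode:
    episode_id: str
    member_id: str
    index_date: Date
    end_date: Date
    has_hospitalization: bool
    trigger: str

    @property
    def episode_length_days(self) -> int:
        return (self.end_date - self.index_date).days + 1

    @property
    def index_year(self) -> int:
        return self.index_date.year

    def pre_episode_window(self, config: PipelineConfig = DEFAULT_CONFIG) -> tuple[Date, Date]:
        return (self.index_date - dt.timedelta(days=config.pre_window_days),
                self.index_date - ONE_DAY)

    def chemo_window(self, config: PipelineConfig = DEFAULT_CONFIG) -> tuple[Date, Date]:
        hi = self.index_date if config.chemo_window_includes_index else self.index_date - ONE_DAY
        return (self.index_date - dt.timedelta(days=config.chemo_window_days), hi)


@dataclass
class AttritionLog:
    """Ordered (criterion label, candidates remaining) counts."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, label: str, remaining: int) -> None:
        self.steps.append((label, remaining))

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)

    def validate(self) -> None:
        counts = [n for _, n in self.steps]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AssertionError(f"attrition counts increased: {self.steps}")


# ---------------------------------------------------------------------------
# claim-level predicates


def _claim_has_dx(claim: MedicalClaim, codes: frozenset[str]) -> bool:
    return any(d in codes for d in claim.dx_codes)


def _claim_has_proc(claim: MedicalClaim, codes: frozenset[str]) -> bool:
    return any(p in codes for p in claim.proc_codes)


def chemo_dates(dataset: ClaimsDataset, member_id: str, codesets: CodeSets) -> list[Date]:
    """Sorted distinct dates with a chemo/biologic pharmacy fill or procedure."""
    chemo = codesets.chemo_codes
    mc = dataset.member_claims(member_id)
    dates: set[Date] = set()
    for day, claims in mc.pharmacy_by_date.items():
        if any(c.drug_code in chemo for c in claims):
            dates.add(day)
    for day, claims in mc.medical_by_date.items():
        if any(_claim_has_proc(c, chemo) for c in claims):
            dates.add(day)
    return sorted(dates)


def fn_dx_dates(dataset: ClaimsDataset, member_id: str, codesets: CodeSets) -> list[Date]:
    """Sorted distinct dates with any neutropenia/infection/fever diagnosis."""
    fn = codesets.fn_dx
    mc = dataset.member_claims(member_id)
    return sorted(
        day for day, claims in mc.medical_by_date.items()
        if any(_claim_has_dx(c, fn) for c in claims)
    )


def _oral_antibiotic_evidence(drugs_filled: set[str], codesets: CodeSets) -> bool:
    for combo in codesets.oral_antibiotic_combinations:
        if all(drugs_filled & codesets[set_name] for set_name in combo):
            return True
    return False


# ---------------------------------------------------------------------------
# detection


def detect_candidates(
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[CandidateIndexEvent]:
    """All (member, date) pairs meeting either episode definition.

    At most one candidate per member-date; when both definitions fire on
    the same date the candidate is recorded as ``inpatient_def``.
    """
    neut = codesets["neutropenia_dx"]
    inffev = codesets.infection_fever_dx
    parenteral = codesets["nccn_parenteral_antibiotic_proc"]

    candidates: list[CandidateIndexEvent] = []
    for member_id in dataset.member_ids_with_claims():
        mc = dataset.member_claims(member_id)
        for day in sorted(mc.medical_by_date):
            claims = mc.medical_by_date[day]
            inpatient = [c for c in claims if c.setting == "inpatient"]
            outpatient = [c for c in claims if c.setting != "inpatient"]

            trigger = None
            trigger_claims: list[str] = []

            if _definition_dx_met(inpatient, neut, inffev, config):
                trigger = "inpatient_def"
                trigger_claims = [c.claim_id for c in inpatient]
            elif _definition_dx_met(outpatient, neut, inffev, config):
                drugs = {c.drug_code for c in mc.pharmacy_by_date.get(day, [])}
                abx = _oral_antibiotic_evidence(drugs, codesets) or any(
                    _claim_has_proc(c, parenteral) for c in claims
                )
                if abx:
                    trigger = "outpatient_def"
                    trigger_claims = [c.claim_id for c in outpatient]

            if trigger is not None:
                candidates.append(
                    CandidateIndexEvent(member_id, day, trigger, tuple(sorted(trigger_claims)))
                )
    return candidates


def _definition_dx_met(claims, neut, inffev, config: PipelineConfig) -> bool:
    if config.require_same_claim_dx:
        return any(_claim_has_dx(c, neut) and _claim_has_dx(c, inffev) for c in claims)
    dx = {d for c in claims for d in c.dx_codes}
    return bool(dx & neut) and bool(dx & inffev)


# ---------------------------------------------------------------------------
# qualification


def qualify(
    candidate: CandidateIndexEvent,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
    *,
    prior_episode_end: Date | None = None,
) -> Rejection | None:
    """Evaluate the inclusion/exclusion criteria for one candidate.

    Returns ``None`` when the candidate qualifies, otherwise a
    :class:`Rejection` carrying the first failing criterion label in the
    fixed evaluation order.  ``prior_episode_end`` marks the candidate as a
    subsequent episode of its member, in which case the clean-pre-period
    criterion is governed by the washout gap rule (when so configured).
    """
    index = candidate.index_date
    pre_lo = index - dt.timedelta(days=config.pre_window_days)
    pre_hi = index - ONE_DAY
    mc = dataset.member_claims(candidate.member_id)

    # (a) chemo/biologic within the treatment window
    chemo_lo = index - dt.timedelta(days=config.chemo_window_days)
    chemo_hi = index if config.chemo_window_includes_index else pre_hi
    cdates = chemo_dates(dataset, candidate.member_id, codesets)
    if not any(chemo_lo <= d <= chemo_hi for d in cdates):
        return Rejection(candidate, "chemo_within_window")

    # (b) continuous enrollment over the pre-episode period through index
    if not dataset.is_enrolled(candidate.member_id, pre_lo, index):
        return Rejection(candidate, "continuous_enrollment")

    # (c) clean pre-period (first episode) / washout-governed (subsequent)
    skip_clean = prior_episode_end is not None and config.subsequent_episode_rule == "washout_gap"
    if not skip_clean:
        fn_days = fn_dx_dates(dataset, candidate.member_id, codesets)
        if any(pre_lo <= d <= pre_hi for d in fn_days):
            return Rejection(candidate, "clean_pre_period")

    # (d) no bone marrow / stem-cell transplant or CAR-T procedure
    bmt = codesets["bmt_sct_cart_proc"]
    for day, claims in mc.medical_by_date.items():
        if pre_lo <= day <= pre_hi and any(_claim_has_proc(c, bmt) for c in claims):
            return Rejection(candidate, "no_bmt_sct_cart")

    # (e) no ALL/AML/CML/MDS diagnosis in the pre-episode period
    heme = codesets["excluded_heme_dx"]
    for day, claims in mc.medical_by_date.items():
        if pre_lo <= day <= pre_hi and any(_claim_has_dx(c, heme) for c in claims):
            return Rejection(candidate, "no_excluded_heme_malignancy")

    # (f) no COVID-19 diagnosis in the configured exclusion window
    covid = codesets["covid_dx"]
    covid_hi = index if config.covid_exclusion_includes_index else pre_hi
    for day, claims in mc.medical_by_date.items():
        if pre_lo <= day <= covid_hi and any(_claim_has_dx(c, covid) for c in claims):
            return Rejection(candidate, "no_covid19")

    return None


# ---------------------------------------------------------------------------
# termination


def terminate_episode(
    candidate: CandidateIndexEvent,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[Date, bool]:
    """End date and hospitalization flag for a qualified index date.

    The provisional end is the earlier of the next incident chemotherapy
    strictly after the index date and index + cap.  An FN-related inpatient
    stay admitted in the provisional window whose discharge runs past the
    provisional end extends the episode to its discharge date.
    """
    index = candidate.index_date
    cap_end = index + dt.timedelta(days=config.episode_cap_days)
    nxt = [d for d in chemo_dates(dataset, candidate.member_id, codesets) if d > index]
    provisional_end = min(nxt[0], cap_end) if nxt else cap_end

    fn = codesets.fn_dx
    mc = dataset.member_claims(candidate.member_id)
    end = provisional_end
    for day, claims in mc.medical_by_date.items():
        if not index <= day <= provisional_end:
            continue
        for c in claims:
            if c.setting == "inpatient" and _claim_has_dx(c, fn) and c.discharge_date is not None:
                if c.discharge_date > end:
                    end = c.discharge_date

    has_hosp = any(
        index <= day <= end and any(c.setting == "inpatient" for c in claims)
        for day, claims in mc.medical_by_date.items()
    )
    return end, has_hosp


# ---------------------------------------------------------------------------
# washout


def washout_gap_ok(
    prior_end: Date,
    next_index: Date,
    fn_days: list[Date],
    washout_days: int,
) -> bool:
    """True iff >= ``washout_days`` consecutive diagnosis-free days exist
    strictly between ``prior_end`` and ``next_index``."""
    points = sorted([prior_end] + [d for d in fn_days if prior_end < d < next_index] + [next_index])
    return any((b - a).days - 1 >= washout_days for a, b in zip(points, points[1:]))


def apply_washout(
    episodes: list[FNEpisode],
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[FNEpisode]:
    """Retain a member's first episode and any later episode separated from
    the previously retained one by a >= 30-day diagnosis-free gap."""
    by_member: dict[str, list[FNEpisode]] = {}
    for ep in episodes:
        by_member.setdefault(ep.member_id, []).append(ep)

    retained: list[FNEpisode] = []
    for member_id in sorted(by_member):
        eps = sorted(by_member[member_id], key=lambda e: e.index_date)
        fn_days = fn_dx_dates(dataset, member_id, codesets)
        prior_end: Date | None = None
        for ep in eps:
            if prior_end is None or washout_gap_ok(prior_end, ep.index_date, fn_days,
                                                   config.washout_days):
                retained.append(ep)
                prior_end = ep.end_date
    return retained


# ---------------------------------------------------------------------------
# full pipeline


def build_cohort(
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[FNEpisode], AttritionLog]:
    """Compose detect -> qualify -> terminate -> washout.

    Members are processed chronologically so that a candidate is judged a
    "subsequent" episode only relative to episodes actually retained before
    it.  The attrition log counts candidates surviving each criterion in
    the fixed order, ending with the washout step.
    """
    candidates = detect_candidates(dataset, codesets, config)

    by_member: dict[str, list[CandidateIndexEvent]] = {}
    for cand in candidates:
        by_member.setdefault(cand.member_id, []).append(cand)

    outcome: dict[CandidateIndexEvent, str] = {}  # criterion label | "retained"
    episodes: list[FNEpisode] = []

    for member_id in sorted(by_member):
        cands = sorted(by_member[member_id], key=lambda c: c.index_date)
        fn_days = fn_dx_dates(dataset, member_id, codesets)
        prior_end: Date | None = None
        for cand in cands:
            rej = qualify(cand, dataset, codesets, config, prior_episode_end=prior_end)
            if rej is not None:
                outcome[cand] = rej.reason
                continue
            if prior_end is not None and not washout_gap_ok(
                prior_end, cand.index_date, fn_days, config.washout_days
            ):
                outcome[cand] = "washout"
                continue
            end, has_hosp = terminate_episode(cand, dataset, codesets, config)
            episodes.append(
                FNEpisode(
                    episode_id=f"{member_id}:{cand.index_date.isoformat()}",
                    member_id=member_id,
                    index_date=cand.index_date,
                    end_date=end,
                    has_hospitalization=has_hosp,
                    trigger=cand.trigger,
                )
            )
            outcome[cand] = "retained"
            prior_end = end

    log = AttritionLog()
    log.record("candidates", len(candidates))
    remaining = len(candidates)
    # candidates rejected at criterion i survived criteria 1..i-1
    for label in CRITERIA:
        remaining -= sum(1 for v in outcome.values() if v == label)
        log.record(label, remaining)
    remaining -= sum(1 for v in outcome.values() if v == "washout")
    log.record("washout", remaining)
    log.validate()
    assert remaining == len(episodes)

    episodes.sort(key=lambda e: (e.member_id, e.index_date))
    return episodes, log


def episodes_to_frame(episodes: list[FNEpisode]):
    """Episode list as a pandas DataFrame (one row per episode)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "episode_id": e.episode_id,
                "member_id": e.member_id,
                "index_date": e.index_date.isoformat(),
                "end_date": e.end_date.isoformat(),
                "episode_length_days": e.episode_length_days,
                "has_hospitalization": e.has_hospitalization,
                "index_year": e.index_year,
                "trigger": e.trigger,
            }
            for e in episodes
        ],
        columns=["episode_id", "member_id", "index_date", "end_date",
                 "episode_length_days", "has_hospitalization", "index_year", "trigger"],
    )
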