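"""Episode-level clinical classification.

For each qualified episode this module derives:

* the FN-risk category of the pre-episode chemotherapy regimen (highest
  risk among all configured regimens matched in the 30-day treatment
  window; unmatched regimens are low/undefined risk);
* GCSF and antimicrobial exposure split into prophylactic use (on the date
  of, or within 4 days after, the first chemotherapy administration) and
  treatment use (any later use in the window) — the two are not mutually
  exclusive — with GCSF further split short- vs long-acting;
* the comorbidity score (weighted sum over configured condition categories
  evidenced in the 180-day pre-episode window) and its category
  (0, >0–<2, >=2);
* the six FN risk-factor flags (age >=65 at index, bone metastasis,
  surgery, radiation, severe liver dysfunction, kidney dysfunction),
  assessed independently;
* cancer-site group membership (a set of flags — an episode may carry
  several cancer sites) and the age category.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel import (CANCER_GROUP_SETS, CANCER_GROUPS, RISK_ORDER,
                        ClaimsDataset, CodeSets, Date, Member)
from .episode_builder import FNEpisode, ONE_DAY

RISK_FACTORS = ("older_age_ge65", "bone_metastasis", "surgery", "radiation",
                "severe_liver_dysfunction", "kidney_dysfunction")

AGE_CATEGORIES = ("lt18", "a18_59", "a60_74", "ge75")
NCI_CATEGORIES = ("zero", "gt0_lt2", "ge2")


@dataclass(frozen=True)
class TreatmentProfile:
    chemo_risk: str
    gcsf_prophylactic: bool
    gcsf_treatment: bool
    gcsf_long_prophylactic: bool
    gcsf_short_prophylactic: bool
    gcsf_long_treatment: bool
    gcsf_short_treatment: bool
    antimicrobial_prophylactic: bool
    antimicrobial_treatment: bool

    @property
    def gcsf_any(self) -> bool:
        return self.gcsf_prophylactic or self.gcsf_treatment

    @property
    def antimicrobial_any(self) -> bool:
        return self.antimicrobial_prophylactic or self.antimicrobial_treatment


@dataclass(frozen=True)
class ClinicalProfile:
    nci_cci_score: float
    nci_category: str
    risk_factors: dict
    cancer_groups: frozenset[str]
    age_years: int
    age_category: str

    @property
    def any_risk_factor(self) -> bool:
        return any(self.risk_factors.values())


def _window(episode: FNEpisode, config: PipelineConfig) -> tuple[Date, Date]:
    lo, hi = episode.pre_episode_window(config)
    if config.lookback_includes_index:
        hi = episode.index_date
    return lo, hi


def _dx_in_window(dataset: ClaimsDataset, member_id: str, codes, lo: Date, hi: Date) -> bool:
    mc = dataset.member_claims(member_id)
    for day, claims in mc.medical_by_date.items():
        if lo <= day <= hi and any(d in codes for c in claims for d in c.dx_codes):
            return True
    return False


def _code_in_window(dataset: ClaimsDataset, member_id: str, codes, lo: Date, hi: Date) -> bool:
    """Any dx, procedure, or pharmacy drug code from ``codes`` in [lo, hi]."""
    mc = dataset.member_claims(member_id)
    for day, claims in mc.medical_by_date.items():
        if lo <= day <= hi:
            for c in claims:
                if any(d in codes for d in c.dx_codes) or any(p in codes for p in c.proc_codes):
                    return True
    for day, claims in mc.pharmacy_by_date.items():
        if lo <= day <= hi and any(c.drug_code in codes for c in claims):
            return True
    return False


# ---------------------------------------------------------------------------
# chemotherapy FN-risk


def _drug_dates_in_window(dataset: ClaimsDataset, member_id: str, codes, lo: Date, hi: Date) -> list[Date]:
    mc = dataset.member_claims(member_id)
    days: set[Date] = set()
    for day, claims in mc.pharmacy_by_date.items():
        if lo <= day <= hi and any(c.drug_code in codes for c in claims):
            days.add(day)
    for day, claims in mc.medical_by_date.items():
        if lo <= day <= hi and any(any(p in codes for p in c.proc_codes) for c in claims):
            days.add(day)
    return sorted(days)


def classify_chemo_risk(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> str:
    """Highest FN-risk category among regimens matched in the chemo window.

    A regimen matches when every one of its drugs is evidenced in the
    30-day treatment window, its conditional dx requirement (if any) is
    evidenced in the pre-episode window, and its minimum administration
    count (if any) is met over the 180-day lookback.
    """
    chemo_lo, chemo_hi = episode.chemo_window(config)
    pre_lo, pre_hi = _window(episode, config)

    best = "low_undefined"
    for regimen in codesets.regimens:
        window_days = _drug_dates_in_window(dataset, episode.member_id, regimen.drugs,
                                            chemo_lo, chemo_hi)
        if not window_days:
            continue
        drugs_seen: set[str] = set()
        mc = dataset.member_claims(episode.member_id)
        for day in window_days:
            for c in mc.pharmacy_by_date.get(day, []):
                if c.drug_code in regimen.drugs:
                    drugs_seen.add(c.drug_code)
            for c in mc.medical_by_date.get(day, []):
                drugs_seen.update(p for p in c.proc_codes if p in regimen.drugs)
        if drugs_seen != set(regimen.drugs):
            continue
        if regimen.requires_dx is not None and not _dx_in_window(
            dataset, episode.member_id, codesets[regimen.requires_dx], pre_lo, pre_hi
        ):
            continue
        if regimen.min_admin_count > 1:
            lookback_days = _drug_dates_in_window(dataset, episode.member_id, regimen.drugs,
                                                  pre_lo, pre_hi)
            if len(lookback_days) < regimen.min_admin_count:
                continue
        if RISK_ORDER[regimen.risk] > RISK_ORDER[best]:
            best = regimen.risk
    return best


# ---------------------------------------------------------------------------
# prophylaxis vs treatment exposure


def _exposure_flags(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    codes,
    config: PipelineConfig,
) -> tuple[bool, bool]:
    """(prophylactic, treatment) flags for drug/procedure ``codes`` in the
    chemo window, anchored at the first chemotherapy administration."""
    chemo_lo, chemo_hi = episode.chemo_window(config)
    chemo_days = _drug_dates_in_window(dataset, episode.member_id, codesets.chemo_codes,
                                       chemo_lo, chemo_hi)
    use_days = _drug_dates_in_window(dataset, episode.member_id, codes, chemo_lo, chemo_hi)
    if not use_days:
        return False, False
    if not chemo_days:
        # exposure without an anchoring chemo administration: treatment use
        return False, True
    first_chemo = chemo_days[0]
    proph_hi = first_chemo + dt.timedelta(days=config.prophylaxis_window_days)
    proph = any(first_chemo <= d <= proph_hi for d in use_days)
    treat = any(not (first_chemo <= d <= proph_hi) for d in use_days)
    return proph, treat


def classify_gcsf(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    long_p, long_t = _exposure_flags(episode, dataset, codesets, codesets["gcsf_long"], config)
    short_p, short_t = _exposure_flags(episode, dataset, codesets, codesets["gcsf_short"], config)
    return {
        "gcsf_prophylactic": long_p or short_p,
        "gcsf_treatment": long_t or short_t,
        "gcsf_long_prophylactic": long_p,
        "gcsf_short_prophylactic": short_p,
        "gcsf_long_treatment": long_t,
        "gcsf_short_treatment": short_t,
    }


def classify_antimicrobial(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    proph, treat = _exposure_flags(episode, dataset, codesets, codesets.antimicrobial_all, config)
    return {"antimicrobial_prophylactic": proph, "antimicrobial_treatment": treat}


def classify_treatments(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> TreatmentProfile:
    gcsf = classify_gcsf(episode, dataset, codesets, config)
    am = classify_antimicrobial(episode, dataset, codesets, config)
    return TreatmentProfile(
        chemo_risk=classify_chemo_risk(episode, dataset, codesets, config),
        **gcsf, **am,
    )


# ---------------------------------------------------------------------------
# comorbidity score


def nci_category(score: float) -> str:
    if score <= 0:
        return "zero"
    if score < 2:
        return "gt0_lt2"
    return "ge2"


def score_nci_cci(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[float, str]:
    """Weighted comorbidity sum over the pre-episode window.

    Each configured condition contributes its weight at most once when at
    least one of its diagnosis codes appears in the lookback window.
    """
    lo, hi = _window(episode, config)
    score = 0.0
    for cond in codesets.cci_conditions.values():
        if _dx_in_window(dataset, episode.member_id, cond.codes, lo, hi):
            score += cond.weight
    return score, nci_category(score)


# ---------------------------------------------------------------------------
# risk factors, cancer groups, age


def age_at(index_date: Date, birth_year: int) -> int:
    return index_date.year - birth_year


def age_category(age: int) -> str:
    if age < 18:
        return "lt18"
    if age <= 59:
        return "a18_59"
    if age <= 74:
        return "a60_74"
    return "ge75"


def flag_risk_factors(
    episode: FNEpisode,
    member: Member,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict:
    lo, hi = _window(episode, config)
    mid = episode.member_id
    return {
        "older_age_ge65": age_at(episode.index_date, member.birth_year) >= 65,
        "bone_metastasis": _dx_in_window(dataset, mid, codesets["bone_met_dx"], lo, hi),
        "surgery": _code_in_window(dataset, mid, codesets["surgery_proc"], lo, hi),
        "radiation": _code_in_window(dataset, mid, codesets["radiation_codes"], lo, hi),
        "severe_liver_dysfunction": _dx_in_window(dataset, mid, codesets["liver_dysfunction_dx"], lo, hi),
        "kidney_dysfunction": _dx_in_window(dataset, mid, codesets["kidney_dysfunction_dx"], lo, hi),
    }


def assign_cancer_group(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> frozenset[str]:
    """Cancer-site groups evidenced in the pre-episode window (may be several)."""
    lo, hi = _window(episode, config)
    return frozenset(
        group for group, set_name in CANCER_GROUP_SETS.items()
        if _dx_in_window(dataset, episode.member_id, codesets[set_name], lo, hi)
    )


def classify_clinical(
    episode: FNEpisode,
    member: Member,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> ClinicalProfile:
    score, cat = score_nci_cci(episode, dataset, codesets, config)
    age = age_at(episode.index_date, member.birth_year)
    return ClinicalProfile(
        nci_cci_score=score,
        nci_category=cat,
        risk_factors=flag_risk_factors(episode, member, dataset, codesets, config),
        cancer_groups=assign_cancer_group(episode, dataset, codesets, config),
        age_years=age,
        age_category=age_category(age),
    )


# ---------------------------------------------------------------------------
# cohort-level table


def classify_episodes(
    episodes,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One classification row per episode (treatments + clinical profile)."""
    rows = []
    for ep in episodes:
        member = dataset.members.get(ep.member_id)
        if member is None:
            raise KeyError(f"episode {ep.episode_id} references unknown member {ep.member_id}")
        tp = classify_treatments(ep, dataset, codesets, config)
        cp = classify_clinical(ep, member, dataset, codesets, config)
        row = {
            "episode_id": ep.episode_id,
            "member_id": ep.member_id,
            "index_year": ep.index_year,
            "has_hospitalization": ep.has_hospitalization,
            "episode_length_days": ep.episode_length_days,
            "chemo_risk": tp.chemo_risk,
            "gcsf_any": tp.gcsf_any,
            "gcsf_prophylactic": tp.gcsf_prophylactic,
            "gcsf_treatment": tp.gcsf_treatment,
            "gcsf_long_prophylactic": tp.gcsf_long_prophylactic,
            "gcsf_short_prophylactic": tp.gcsf_short_prophylactic,
            "gcsf_long_treatment": tp.gcsf_long_treatment,
            "gcsf_short_treatment": tp.gcsf_short_treatment,
            "antimicrobial_any": tp.antimicrobial_any,
            "antimicrobial_prophylactic": tp.antimicrobial_prophylactic,
            "antimicrobial_treatment": tp.antimicrobial_treatment,
            "nci_cci_score": cp.nci_cci_score,
            "nci_category": cp.nci_category,
            "any_risk_factor": cp.any_risk_factor,
            "age_years": cp.age_years,
            "age_category": cp.age_category,
            "sex": member.sex,
            "payer": member.payer,
            "region": member.region,
        }
        for rf in RISK_FACTORS:
            row[f"rf_{rf}"] = cp.risk_factors[rf]
        for group in CANCER_GROUPS:
            row[f"cancer_{group}"] = group in cp.cancer_groups
        rows.append(row)
    return pd.DataFrame(rows)
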