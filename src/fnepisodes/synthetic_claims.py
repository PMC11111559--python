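"""Seeded synthetic administrative-claims generator.

Real FN claims data is proprietary, so this module fabricates datasets
with the statistical structure the pipeline assumes: members with
enrollment spans, pre-index chemotherapy courses, index events meeting the
inpatient or outpatient case definition, configurable hospitalization
probability, lognormal episode costs moment-matched to target mean/SD,
planted comorbidity / risk-factor / cancer-site prevalences, and
GCSF/antimicrobial exposure with known prophylaxis-vs-treatment timing.

Every planted episode is recorded in a ground-truth ledger — including
members planted with a deliberate qualification VIOLATION and the
criterion expected to reject them — so tests never re-derive intent from
the claims themselves.  Output is deterministic for a given seed.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel import (ClaimsDataset, CodeSets, Date, EnrollmentSpan,
                        Member, MedicalClaim, PharmacyClaim, load_codesets,
                        load_cpi_table, ConfigError)

DAY = dt.timedelta(days=1)

VIOLATION_TYPES = (
    "chemo_within_window",
    "continuous_enrollment",
    "clean_pre_period",
    "no_bmt_sct_cart",
    "no_excluded_heme_malignancy",
    "no_covid19",
    "washout",
)


def lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched lognormal parameters (meanlog, sdlog).

    sdlog^2 = ln(1 + (sd/mean)^2); meanlog = ln(mean) - sdlog^2 / 2, so the
    analytic lognormal mean and SD equal the inputs exactly.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    sdlog2 = math.log(1.0 + (sd / mean) ** 2)
    meanlog = math.log(mean) - sdlog2 / 2.0
    return meanlog, math.sqrt(sdlog2)


class GeneratorConfig(BaseModel):
    """Study conditions the generator emulates.

    Default rates are the central figures of the study population this
    package models: 91% of episodes hospitalized, chemotherapy FN-risk mix
    19.7/49.4/30.9 (high/intermediate/low-undefined), 40% of episodes with
    GCSF use of which 67.2% prophylactic and 58.4% treatment (not mutually
    exclusive), 24.1% with antimicrobial use, FN-related episode cost
    lognormal with mean $26,868 / SD $41,183 when hospitalized and
    $7,738 / $15,030 otherwise (2021 USD), and risk-factor / comorbidity /
    cancer-site prevalences as listed below.
    """

    n_members: int = Field(200, ge=0)
    n_violation_members: int = Field(0, ge=0)
    study_start: Date = dt.date(2014, 7, 1)
    study_end: Date = dt.date(2021, 12, 31)
    seed: int = 0

    p_hospitalized_episode: float = Field(0.91, ge=0.0, le=1.0)
    p_second_episode: float = Field(0.029, ge=0.0, le=1.0)

    # episode termination: probability of a next chemotherapy administration
    # and its gap after the index date, in days
    p_next_chemo: float = Field(0.85, ge=0.0, le=1.0)
    next_chemo_gap: tuple[int, int] = (7, 45)

    # FN-related total episode cost (2021 USD), by hospitalization status
    fn_cost_hosp_mean: float = Field(26868.0, gt=0)
    fn_cost_hosp_sd: float = Field(41183.0, gt=0)
    fn_cost_nonhosp_mean: float = Field(7738.0, gt=0)
    fn_cost_nonhosp_sd: float = Field(15030.0, gt=0)

    # additional non-FN-related cost during the episode (2021 USD)
    extra_cost_mean: float = Field(10723.0, gt=0)
    extra_cost_sd: float = Field(15000.0, gt=0)

    # inpatient length of stay (days) for FN hospitalizations
    los_mean: float = Field(6.9, gt=0)
    los_sd: float = Field(7.2, gt=0)

    chemo_risk_mix: dict[str, float] = {
        "high": 0.197, "intermediate": 0.494, "low_undefined": 0.309,
    }

    gcsf_any_rate: float = Field(0.40, ge=0.0, le=1.0)
    gcsf_prophylactic_given_use: float = Field(0.672, ge=0.0, le=1.0)
    gcsf_treatment_given_use: float = Field(0.584, ge=0.0, le=1.0)
    gcsf_long_share_prophylactic: float = Field(0.928, ge=0.0, le=1.0)
    gcsf_long_share_treatment: float = Field(0.769, ge=0.0, le=1.0)

    antimicrobial_any_rate: float = Field(0.241, ge=0.0, le=1.0)
    antimicrobial_prophylactic_given_use: float = Field(0.284, ge=0.0, le=1.0)
    antimicrobial_treatment_given_use: float = Field(0.793, ge=0.0, le=1.0)

    risk_factor_prevalence: dict[str, float] = {
        "bone_metastasis": 0.17, "surgery": 0.86, "radiation": 0.24,
        "severe_liver_dysfunction": 0.033, "kidney_dysfunction": 0.142,
    }
    comorbidity_prevalence: dict[str, float] = {
        "diabetes": 0.20, "copd": 0.15, "renal_disease": 0.10,
        "congestive_heart_failure": 0.10, "myocardial_infarction": 0.08,
        "cerebrovascular_disease": 0.09, "mild_liver_disease": 0.06,
        "diabetes_with_complications": 0.10, "peptic_ulcer_disease": 0.03,
    }
    cancer_group_prevalence: dict[str, float] = {
        "NHL": 0.144, "CLL": 0.021, "other_hematologic": 0.072,
        "breast": 0.273, "lung": 0.152, "colorectal": 0.111,
        "prostate": 0.036, "other_solid": 0.476,
    }

    age_mean: float = 55.4
    age_sd: float = 15.0
    p_female: float = Field(0.606, ge=0.0, le=1.0)
    payer_mix: dict[str, float] = {
        "commercial": 0.875, "medicare": 0.074, "medicaid": 0.021, "unknown": 0.030,
    }
    region_mix: dict[str, float] = {
        "northeast": 0.177, "midwest": 0.268, "south": 0.400,
        "west": 0.151, "unknown": 0.004,
    }

    @model_validator(mode="after")
    def _check_feasible(self):
        for name, mix in (("chemo_risk_mix", self.chemo_risk_mix),
                          ("payer_mix", self.payer_mix), ("region_mix", self.region_mix)):
            if any(v < 0 for v in mix.values()) or not mix:
                raise ValueError(f"{name} must be non-negative and non-empty")
        both = self.gcsf_prophylactic_given_use + self.gcsf_treatment_given_use
        if both < 1.0 - 1e-9 and self.gcsf_any_rate > 0:
            # users must be prophylactic and/or treatment; the two shares
            # must cover every user
            raise ValueError("gcsf prophylactic+treatment shares must sum to >= 1")
        if (self.antimicrobial_prophylactic_given_use
                + self.antimicrobial_treatment_given_use) < 1.0 - 1e-9 \
                and self.antimicrobial_any_rate > 0:
            raise ValueError("antimicrobial prophylactic+treatment shares must sum to >= 1")
        lo = self.study_start + dt.timedelta(days=200)
        hi = self.study_end - dt.timedelta(days=135)
        if lo > hi:
            raise ValueError("study window too short for pre-episode and follow-up periods")
        return self


@dataclass
class GroundTruthEpisode:
    """One planted episode intent; the oracle record for tests."""

    member_id: str
    index_date: Date
    expected_end_date: Date
    hospitalized: bool
    trigger: str
    fn_cost_2021: float
    extra_cost_2021: float
    chemo_risk: str
    gcsf_prophylactic: bool
    gcsf_treatment: bool
    gcsf_long_prophylactic: bool
    gcsf_short_prophylactic: bool
    gcsf_long_treatment: bool
    gcsf_short_treatment: bool
    antimicrobial_prophylactic: bool
    antimicrobial_treatment: bool
    expected_cci_score: float
    risk_factors: dict
    cancer_groups: list
    age_years: int
    violation: str | None = None


#: regimen plants per risk level: (drug codes, admin gap list in days
#: relative to first chemo, minimum lag of first chemo before index)
_REGIMEN_PLANTS = {
    "high": (("J9000", "J9070"), (0, 14), 16),          # dose-dense AC, 2 cycles
    "intermediate": (("J9045", "J9267"), (0,), 8),       # carboplatin + paclitaxel
    "low_undefined": (("J9201",), (0,), 8),              # gemcitabine mono
}

_NEUTROPENIA = "D70.9"
_FEVER = "R50.9"
_UNRELATED_DX = "Z00.00"
_UNRELATED_DRUG = "OTH001"
_ORAL_ABX = "LVX500"  # levofloxacin singleton combination

_RF_PLANTS = {
    "bone_metastasis": ("dx", "C79.51"),
    "surgery": ("proc", "19303"),
    "radiation": ("proc", "77401"),
    "severe_liver_dysfunction": ("dx", "K72.90"),
    "kidney_dysfunction": ("dx", "N18.5"),
}

_CANCER_PLANTS = {
    "NHL": "C82.90", "CLL": "C91.10", "other_hematologic": "C81.90",
    "breast": "C50.911", "lung": "C34.90", "colorectal": "C18.9",
    "prostate": "C61", "other_solid": "C56.9",
}


class _Builder:
    def __init__(self, config: GeneratorConfig, codesets: CodeSets,
                 cpi_table: dict[int, float]) -> None:
        self.config = config
        self.codesets = codesets
        self.cpi = cpi_table
        self.rng = np.random.default_rng(config.seed)
        self.members: dict[str, Member] = {}
        self.enrollment: list[EnrollmentSpan] = []
        self.medical: list[MedicalClaim] = []
        self.pharmacy: list[PharmacyClaim] = []
        self.ledger: list[GroundTruthEpisode] = []
        self._claim_seq = 0

    # -- helpers ----------------------------------------------------------
    def _cid(self, member_id: str) -> str:
        self._claim_seq += 1
        return f"{member_id}-C{self._claim_seq:06d}"

    def _deflate(self, cost_2021: float, year: int) -> float:
        if year not in self.cpi:
            raise ConfigError(f"CPI table has no index for year {year}")
        return round(cost_2021 * self.cpi[year] / self.cpi[2021], 2)

    def _choice(self, mix: dict[str, float]) -> str:
        names = list(mix)
        probs = np.array([mix[n] for n in names], dtype=float)
        probs = probs / probs.sum()
        return names[int(self.rng.choice(len(names), p=probs))]

    def _med(self, member_id: str, day: Date, setting: str, dx=(), proc=(),
             paid_2021: float = 0.0, discharge: Date | None = None) -> None:
        self.medical.append(
            MedicalClaim(self._cid(member_id), member_id, day, discharge, setting,
                         tuple(dx), tuple(proc), self._deflate(paid_2021, day.year))
        )

    def _rx(self, member_id: str, day: Date, drug: str, paid_2021: float = 0.0) -> None:
        self.pharmacy.append(
            PharmacyClaim(self._cid(member_id), member_id, day, drug,
                          self._deflate(paid_2021, day.year))
        )

    def _rand_day(self, lo: Date, hi: Date) -> Date:
        span = (hi - lo).days
        return lo + dt.timedelta(days=int(self.rng.integers(0, span + 1)))

    def _draw_index_date(self) -> Date:
        return self._rand_day(self.config.study_start + dt.timedelta(days=200),
                              self.config.study_end - dt.timedelta(days=135))

    # -- member-level plants ----------------------------------------------
    def add_member(self, member_id: str, index_date: Date) -> Member:
        cfg = self.config
        age = int(np.clip(round(self.rng.normal(cfg.age_mean, cfg.age_sd)), 1, 90))
        member = Member(
            member_id=member_id,
            birth_year=index_date.year - age,
            sex="female" if self.rng.random() < cfg.p_female else "male",
            payer=self._choice(cfg.payer_mix),
            region=self._choice(cfg.region_mix),
        )
        self.members[member_id] = member
        return member

    def plant_background(self, member_id: str, index_date: Date) -> tuple[dict, list, float]:
        """Risk factors, cancer sites, comorbidities in the pre-episode window."""
        cfg = self.config
        lo = index_date - dt.timedelta(days=170)
        hi = index_date - dt.timedelta(days=35)
        planted_codes: set[str] = set()

        rf = {}
        for name, prevalence in cfg.risk_factor_prevalence.items():
            rf[name] = bool(self.rng.random() < prevalence)
            if rf[name]:
                kind, code = _RF_PLANTS[name]
                day = self._rand_day(lo, hi)
                if kind == "dx":
                    self._med(member_id, day, "other_outpatient", dx=[code])
                    planted_codes.add(code)
                else:
                    self._med(member_id, day, "other_outpatient", proc=[code])
        rf_dx_sets = {"bone_metastasis": "bone_met_dx",
                      "severe_liver_dysfunction": "liver_dysfunction_dx",
                      "kidney_dysfunction": "kidney_dysfunction_dx"}

        groups = sorted(
            g for g, prevalence in cfg.cancer_group_prevalence.items()
            if self.rng.random() < prevalence
        )
        for group in groups:
            self._med(member_id, self._rand_day(lo, hi), "other_outpatient",
                      dx=[_CANCER_PLANTS[group]])

        for name, prevalence in cfg.comorbidity_prevalence.items():
            if self.rng.random() < prevalence:
                cond = self.codesets.cci_conditions[name]
                code = sorted(cond.codes)[0]
                self._med(member_id, self._rand_day(lo, hi), "physician_office", dx=[code])
                planted_codes.add(code)

        score = sum(
            cond.weight for cond in self.codesets.cci_conditions.values()
            if planted_codes & cond.codes
        )
        # comorbidity plants can share codes with dx-driven risk factors
        # (e.g. renal disease and kidney dysfunction); the ledger flag is
        # derived from everything planted, not the intent draw alone
        for name, set_name in rf_dx_sets.items():
            rf[name] = rf[name] or bool(planted_codes & self.codesets[set_name])
        return rf, groups, float(score)

    def plant_chemo_course(self, member_id: str, index_date: Date,
                           max_lag: int = 28) -> tuple[str, Date]:
        """Chemo administrations in the treatment window; returns (risk, first chemo date)."""
        risk = self._choice(self.config.chemo_risk_mix)
        drugs, gaps, min_lag = _REGIMEN_PLANTS[risk]
        lag = int(self.rng.integers(min_lag, max(max_lag, min_lag) + 1))
        first = index_date - dt.timedelta(days=lag)
        for gap in gaps:
            day = first + dt.timedelta(days=gap)
            self._med(member_id, day, "other_outpatient", proc=list(drugs), paid_2021=150.0)
        return risk, first

    def plant_exposures(self, member_id: str, index_date: Date, first_chemo: Date) -> dict:
        """GCSF and antimicrobial fills with known prophylaxis/treatment timing."""
        cfg = self.config
        rng = self.rng
        flags = dict.fromkeys(
            ["gcsf_prophylactic", "gcsf_treatment", "gcsf_long_prophylactic",
             "gcsf_short_prophylactic", "gcsf_long_treatment", "gcsf_short_treatment",
             "antimicrobial_prophylactic", "antimicrobial_treatment"], False)
        lag = (index_date - first_chemo).days

        def split_use(p_proph: float, p_treat: float) -> tuple[bool, bool]:
            p_both = max(p_proph + p_treat - 1.0, 0.0)
            p_proph_only = p_proph - p_both
            u = rng.random()
            if u < p_both:
                return True, True
            if u < p_both + p_proph_only:
                return True, False
            return False, True

        if rng.random() < cfg.gcsf_any_rate:
            proph, treat = split_use(cfg.gcsf_prophylactic_given_use,
                                     cfg.gcsf_treatment_given_use)
            if proph:
                offset = int(rng.integers(0, min(4, lag - 1) + 1))
                long_acting = rng.random() < cfg.gcsf_long_share_prophylactic
                drug = "J2505" if long_acting else "J1442"
                self._rx(member_id, first_chemo + dt.timedelta(days=offset), drug, 4000.0)
                flags["gcsf_prophylactic"] = True
                flags["gcsf_long_prophylactic" if long_acting else "gcsf_short_prophylactic"] = True
            if treat and lag >= 6:
                offset = int(rng.integers(5, lag))
                long_acting = rng.random() < cfg.gcsf_long_share_treatment
                drug = "J2505" if long_acting else "J1442"
                self._rx(member_id, first_chemo + dt.timedelta(days=offset), drug, 4000.0)
                flags["gcsf_treatment"] = True
                flags["gcsf_long_treatment" if long_acting else "gcsf_short_treatment"] = True

        if rng.random() < cfg.antimicrobial_any_rate:
            proph, treat = split_use(cfg.antimicrobial_prophylactic_given_use,
                                     cfg.antimicrobial_treatment_given_use)
            if proph:
                offset = int(rng.integers(0, min(4, lag - 1) + 1))
                self._rx(member_id, first_chemo + dt.timedelta(days=offset), "AZM250", 40.0)
                flags["antimicrobial_prophylactic"] = True
            if treat and lag >= 6:
                offset = int(rng.integers(5, lag))
                self._rx(member_id, first_chemo + dt.timedelta(days=offset), "AZM250", 40.0)
                flags["antimicrobial_treatment"] = True
        return flags

    # -- episode plants ----------------------------------------------------
    def plant_episode(self, member_id: str, index_date: Date, *,
                      age_years: int, violation: str | None = None,
                      force_next_chemo: bool = False,
                      max_chemo_lag: int = 28) -> GroundTruthEpisode:
        cfg = self.config
        rng = self.rng

        chemo_risk, first_chemo = self.plant_chemo_course(member_id, index_date,
                                                          max_lag=max_chemo_lag)
        if violation == "chemo_within_window":
            # replace the in-window course: single administration exactly 31
            # days before index, one day outside the window
            self.medical = [c for c in self.medical
                            if not (c.member_id == member_id
                                    and c.service_date >= index_date - dt.timedelta(days=30)
                                    and any(p in self.codesets.chemo_codes for p in c.proc_codes))]
            self._med(member_id, index_date - dt.timedelta(days=31), "other_outpatient",
                      proc=["J9201"], paid_2021=150.0)
            chemo_risk = "low_undefined"
            flags = dict.fromkeys(
                ["gcsf_prophylactic", "gcsf_treatment", "gcsf_long_prophylactic",
                 "gcsf_short_prophylactic", "gcsf_long_treatment", "gcsf_short_treatment",
                 "antimicrobial_prophylactic", "antimicrobial_treatment"], False)
        else:
            flags = self.plant_exposures(member_id, index_date, first_chemo)

        hospitalized = bool(rng.random() < cfg.p_hospitalized_episode)

        # provisional termination
        next_chemo: Date | None = None
        if force_next_chemo or rng.random() < cfg.p_next_chemo:
            gap = int(rng.integers(cfg.next_chemo_gap[0], cfg.next_chemo_gap[1] + 1))
            next_chemo = index_date + dt.timedelta(days=gap)
        cap_end = index_date + dt.timedelta(days=DEFAULT_CONFIG.episode_cap_days)
        provisional_end = min(next_chemo, cap_end) if next_chemo else cap_end

        # FN-related cost and index-event claims
        if hospitalized:
            mean, sd = cfg.fn_cost_hosp_mean, cfg.fn_cost_hosp_sd
        else:
            mean, sd = cfg.fn_cost_nonhosp_mean, cfg.fn_cost_nonhosp_sd
        meanlog, sdlog = lognormal_from_mean_sd(mean, sd)
        fn_cost = round(float(rng.lognormal(meanlog, sdlog)), 2)

        if hospitalized:
            meanlog_l, sdlog_l = lognormal_from_mean_sd(cfg.los_mean, cfg.los_sd)
            los = int(np.clip(round(rng.lognormal(meanlog_l, sdlog_l)), 1, 30))
            discharge = index_date + dt.timedelta(days=los - 1)
            self._med(member_id, index_date, "inpatient",
                      dx=[_NEUTROPENIA, _FEVER], paid_2021=fn_cost, discharge=discharge)
            trigger = "inpatient_def"
            end = max(provisional_end, discharge) if discharge > provisional_end else provisional_end
        else:
            rx_share = round(min(40.0, 0.1 * fn_cost), 2)
            self._med(member_id, index_date, "emergency_room",
                      dx=[_NEUTROPENIA, _FEVER], paid_2021=round(fn_cost - rx_share, 2))
            self._rx(member_id, index_date, _ORAL_ABX, paid_2021=rx_share)
            trigger = "outpatient_def"
            end = provisional_end

        if next_chemo is not None:
            self._med(member_id, next_chemo, "other_outpatient", proc=["J9201"], paid_2021=0.0)

        # non-FN utilization during the episode (all-cause only)
        meanlog_e, sdlog_e = lognormal_from_mean_sd(cfg.extra_cost_mean, cfg.extra_cost_sd)
        extra = round(float(rng.lognormal(meanlog_e, sdlog_e)), 2)
        n_office = 1 + int(rng.poisson(3))
        n_other = 1 + int(rng.poisson(5))
        office_each = round(extra * 0.10 / n_office, 2)
        other_each = round(extra * 0.60 / n_other, 2)
        pharmacy_cost = round(extra - office_each * n_office - other_each * n_other, 2)
        window_hi = min(provisional_end, cap_end)
        for _ in range(n_office):
            self._med(member_id, self._rand_day(index_date, window_hi), "physician_office",
                      dx=[_UNRELATED_DX], paid_2021=office_each)
        for _ in range(n_other):
            self._med(member_id, self._rand_day(index_date, window_hi), "other_outpatient",
                      dx=[_UNRELATED_DX], paid_2021=other_each)
        self._rx(member_id, self._rand_day(index_date, window_hi), _UNRELATED_DRUG,
                 paid_2021=pharmacy_cost)
        extra_total = round(office_each * n_office + other_each * n_other + pharmacy_cost, 2)

        return GroundTruthEpisode(
            member_id=member_id,
            index_date=index_date,
            expected_end_date=end,
            hospitalized=hospitalized,
            trigger=trigger,
            fn_cost_2021=fn_cost,
            extra_cost_2021=extra_total,
            chemo_risk=chemo_risk,
            **flags,
            expected_cci_score=0.0,  # filled by caller
            risk_factors={},
            cancer_groups=[],
            age_years=age_years,
            violation=violation,
        )

    # -- whole members -----------------------------------------------------
    def build_valid_member(self, member_id: str) -> None:
        cfg = self.config
        index_date = self._draw_index_date()
        member = self.add_member(member_id, index_date)
        age = index_date.year - member.birth_year
        rf, groups, score = self.plant_background(member_id, index_date)
        rf_full = dict(rf, older_age_ge65=age >= 65)

        second = self.rng.random() < cfg.p_second_episode
        ep1 = self.plant_episode(member_id, index_date, age_years=age,
                                 force_next_chemo=second)
        ep1.expected_cci_score = score
        ep1.risk_factors = rf_full
        ep1.cancer_groups = groups
        self.ledger.append(ep1)

        last_end = ep1.expected_end_date
        if second:
            idx2 = ep1.expected_end_date + dt.timedelta(days=40)
            if idx2 <= cfg.study_end - dt.timedelta(days=135):
                age2 = idx2.year - member.birth_year
                ep2 = self.plant_episode(member_id, idx2, age_years=age2)
                ep2.risk_factors = dict(rf_full, older_age_ge65=age2 >= 65)
                ep2.cancer_groups = groups
                ep2.expected_cci_score = score  # window shift may drop plants; advisory
                self.ledger.append(ep2)
                last_end = ep2.expected_end_date

        self.enrollment.append(
            EnrollmentSpan(member_id, index_date - dt.timedelta(days=200),
                           last_end + dt.timedelta(days=60))
        )

    def build_violation_member(self, member_id: str, violation: str) -> None:
        index_date = self._draw_index_date()
        member = self.add_member(member_id, index_date)
        age = index_date.year - member.birth_year

        if violation == "washout":
            # a valid first episode, then a second candidate too close to it
            ep1 = self.plant_episode(member_id, index_date, age_years=age,
                                     force_next_chemo=True)
            self.ledger.append(ep1)
            idx2 = ep1.expected_end_date + dt.timedelta(days=20)
            # keep the second chemo course strictly after the first episode's
            # end so it cannot alter the first episode's termination
            ep2 = self.plant_episode(member_id, idx2, age_years=age, violation="washout",
                                     max_chemo_lag=19)
            self.ledger.append(ep2)
            span_end = ep2.expected_end_date + dt.timedelta(days=60)
            self.enrollment.append(
                EnrollmentSpan(member_id, index_date - dt.timedelta(days=200), span_end)
            )
            return

        ep = self.plant_episode(member_id, index_date, age_years=age, violation=violation)
        self.ledger.append(ep)
        pre = index_date - dt.timedelta(days=200)
        span_end = ep.expected_end_date + dt.timedelta(days=60)
        if violation == "continuous_enrollment":
            # enrollment starts inside the 180-day pre-episode period
            self.enrollment.append(
                EnrollmentSpan(member_id, index_date - dt.timedelta(days=150), span_end)
            )
        else:
            self.enrollment.append(EnrollmentSpan(member_id, pre, span_end))

        if violation == "clean_pre_period":
            self._med(member_id, index_date - dt.timedelta(days=60),
                      "other_outpatient", dx=[_FEVER])
        elif violation == "no_bmt_sct_cart":
            self._med(member_id, index_date - dt.timedelta(days=90),
                      "other_outpatient", proc=["38240"])
        elif violation == "no_excluded_heme_malignancy":
            self._med(member_id, index_date - dt.timedelta(days=100),
                      "other_outpatient", dx=["C92.00"])
        elif violation == "no_covid19":
            self._med(member_id, index_date - dt.timedelta(days=20),
                      "other_outpatient", dx=["U07.1"])


def generate_synthetic_claims(
    config: GeneratorConfig | None = None,
    codesets: CodeSets | None = None,
    cpi_table: dict[int, float] | None = None,
) -> tuple[ClaimsDataset, list[GroundTruthEpisode]]:
    """Generate a full synthetic dataset plus its ground-truth ledger.

    Deterministic for a given ``config.seed``.  Episodes of members planted
    without a violation are exactly the episodes ``build_cohort`` retains.
    """
    config = config or GeneratorConfig()
    codesets = codesets or load_codesets()
    cpi_table = cpi_table or load_cpi_table()

    builder = _Builder(config, codesets, cpi_table)
    for i in range(config.n_members):
        builder.build_valid_member(f"M{i:06d}")
    for j in range(config.n_violation_members):
        violation = VIOLATION_TYPES[j % len(VIOLATION_TYPES)]
        builder.build_violation_member(f"V{j:06d}", violation)

    dataset = ClaimsDataset(
        members=builder.members,
        enrollment=builder.enrollment,
        medical=sorted(builder.medical, key=lambda c: (c.member_id, c.service_date, c.claim_id)),
        pharmacy=sorted(builder.pharmacy, key=lambda c: (c.member_id, c.fill_date, c.claim_id)),
    )
    return dataset, builder.ledger


def ledger_to_json(ledger: list[GroundTruthEpisode], path: str | Path) -> None:
    def encode(entry: GroundTruthEpisode) -> dict:
        d = asdict(entry)
        d["index_date"] = entry.index_date.isoformat()
        d["expected_end_date"] = entry.expected_end_date.isoformat()
        return d

    Path(path).write_text(json.dumps([encode(e) for e in ledger], indent=1) + "\n")
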