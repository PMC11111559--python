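"""Tunable windows and interpretation flags for the episode pipeline.

Every day-count window the algorithm uses is collected here so that the
whole rule set can be driven from a single YAML file.  All windows are in
whole calendar days and all intervals are closed on both ends unless a
specific operation documents otherwise.
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    """Windows and rule switches for episode construction and classification.

    Defaults mirror the study design this package implements: a 180-day
    pre-episode lookback, a 30-day chemotherapy treatment period, a 60-day
    episode cap, a 4-day prophylaxis window after the first chemotherapy
    administration, and a 30-day inter-episode washout.
    """

    pre_window_days: int = Field(180, gt=0, description="Pre-episode lookback, days")
    chemo_window_days: int = Field(30, gt=0, description="Chemotherapy treatment period, days")
    episode_cap_days: int = Field(60, gt=0, description="Maximum follow-up after index without extension")
    prophylaxis_window_days: int = Field(4, ge=0, description="Days after first chemo still counted as prophylaxis")
    washout_days: int = Field(30, gt=0, description="Clean gap required between episodes")

    #: include chemotherapy on the index date itself when testing the
    #: 30-day requirement; default excludes it (treatment must precede the
    #: trigger).
    chemo_window_includes_index: bool = False

    #: how the clean-pre-period rule applies to a member's second and later
    #: episodes: "washout_gap" replaces it with the >=30-day clean gap;
    #: "full_clean_period" re-applies the full 180-day clean requirement
    #: (under which multi-episode members are essentially impossible).
    subsequent_episode_rule: Literal["washout_gap", "full_clean_period"] = "washout_gap"

    #: COVID-19 exclusion window: pre-episode period and, when True, the
    #: index date itself.
    covid_exclusion_includes_index: bool = True

    #: whether comorbidity scoring and risk-factor lookback include the
    #: index date in addition to the 180-day pre-period.
    lookback_includes_index: bool = False

    #: require the neutropenia dx and the fever/infection dx to sit on one
    #: claim (True) or merely on same-date claims of the qualifying setting
    #: class (False, default).
    require_same_claim_dx: bool = False

    #: inpatient length-of-stay convention: "inclusive" counts
    #: discharge - admission + 1 (a same-day stay has LOS 1);
    #: "difference" counts discharge - admission.
    los_convention: Literal["inclusive", "difference"] = "inclusive"

    #: oral antibiotic evidence for the outpatient definition: when True,
    #: only the configured combination rules qualify; single agents not
    #: listed as singleton combinations never qualify.
    strict_oral_combinations: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


DEFAULT_CONFIG = PipelineConfig()
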