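"""Healthcare resource utilization and cost attribution.

Every claim dated inside an episode window (inclusive of the index date)
is bucketed by care setting — inpatient, emergency room, physician office,
other outpatient, pharmacy — once on an all-cause basis and once on an
FN-related basis.  A medical claim is FN-related when it carries a
neutropenia, infection, or fever diagnosis; a pharmacy claim when its drug
is a GCSF or antimicrobial; GCSF and antimicrobial exposure during the
episode is additionally tallied as two FN-related treatment categories.
Costs are converted to 2021 dollars with the medical-CPI table before
summarizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .datamodel import ClaimsDataset, CodeSets, ConfigError, MedicalClaim
from .episode_builder import FNEpisode

CATEGORIES = ("inpatient", "emergency_room", "physician_office", "other_outpatient", "pharmacy")
TREATMENT_CATEGORIES = ("gcsf", "antimicrobial")


@dataclass(frozen=True)
class UtilizationRecord:
    episode_id: str
    category: str
    fn_related: bool
    visit_count: int
    inpatient_los_days: int
    cost_nominal: float
    cost_2021: float


def adjust_to_2021(cost_nominal: float, service_year: int, cpi_table: dict[int, float]) -> float:
    """Convert a nominal cost of ``service_year`` into 2021 dollars."""
    if service_year not in cpi_table:
        raise ConfigError(f"CPI table has no index for year {service_year}")
    if 2021 not in cpi_table:
        raise ConfigError("CPI table must include the 2021 reference index")
    return cost_nominal * (cpi_table[2021] / cpi_table[service_year])


def _merge_spans(spans: list[tuple]) -> list[tuple]:
    """Maximal unions of overlapping/contiguous [admit, discharge] spans."""
    if not spans:
        return []
    spans = sorted(spans)
    out = [spans[0]]
    for start, end in spans[1:]:
        last_start, last_end = out[-1]
        if start <= last_end:
            out[-1] = (last_start, max(last_end, end))
        else:
            out.append((start, end))
    return out


def _los(admit, discharge, config: PipelineConfig) -> int:
    days = (discharge - admit).days
    if config.los_convention == "inclusive":
        return max(days + 1, 1)
    return days


def _is_fn_medical(claim: MedicalClaim, codesets: CodeSets) -> bool:
    fn = codesets.fn_dx
    if any(d in fn for d in claim.dx_codes):
        return True
    # FN treatment administered in a medical setting
    tx = codesets.gcsf_all | codesets["nccn_parenteral_antibiotic_proc"]
    return any(p in tx for p in claim.proc_codes)


def attribute_claims(
    episode: FNEpisode,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    cpi_table: dict[int, float],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[UtilizationRecord]:
    """Utilization records for one episode: per category, all-cause and
    FN-related, plus the GCSF/antimicrobial treatment categories."""
    lo, hi = episode.index_date, episode.end_date
    mc = dataset.member_claims(episode.member_id)

    med_in_window = [
        c
        for day, claims in mc.medical_by_date.items()
        if lo <= day <= hi
        for c in claims
    ]
    rx_in_window = [
        c
        for day, claims in mc.pharmacy_by_date.items()
        if lo <= day <= hi
        for c in claims
    ]

    records: list[UtilizationRecord] = []

    def emit(category: str, fn_related: bool, medical: list[MedicalClaim], pharmacy) -> None:
        if category == "inpatient":
            spans = _merge_spans([(c.service_date, c.discharge_date) for c in medical])
            visits = len(spans)
            los = sum(_los(a, d, config) for a, d in spans)
        elif category == "pharmacy":
            visits = len(pharmacy)
            los = 0
        else:
            visits = len({c.service_date for c in medical})
            los = 0
        nominal = sum(c.paid_amount for c in medical) + sum(c.paid_amount for c in pharmacy)
        adjusted = sum(
            adjust_to_2021(c.paid_amount, c.service_date.year, cpi_table) for c in medical
        ) + sum(adjust_to_2021(c.paid_amount, c.fill_date.year, cpi_table) for c in pharmacy)
        if visits or nominal:
            records.append(
                UtilizationRecord(episode.episode_id, category, fn_related,
                                  visits, los, nominal, adjusted)
            )

    fn_rx_codes = codesets.gcsf_all | codesets.antimicrobial_all
    for category in CATEGORIES:
        if category == "pharmacy":
            emit("pharmacy", False, [], rx_in_window)
            emit("pharmacy", True, [], [c for c in rx_in_window if c.drug_code in fn_rx_codes])
        else:
            med = [c for c in med_in_window if c.setting == category]
            emit(category, False, med, [])
            emit(category, True, [c for c in med if _is_fn_medical(c, codesets)], [])

    # FN treatment categories during the episode
    gcsf_rx = [c for c in rx_in_window if c.drug_code in codesets.gcsf_all]
    gcsf_med = [c for c in med_in_window if any(p in codesets.gcsf_all for p in c.proc_codes)]
    am_rx = [c for c in rx_in_window if c.drug_code in codesets.antimicrobial_all]
    am_med = [
        c for c in med_in_window
        if any(p in codesets["nccn_parenteral_antibiotic_proc"] for p in c.proc_codes)
    ]
    for category, med, rx in (("gcsf", gcsf_med, gcsf_rx), ("antimicrobial", am_med, am_rx)):
        visits = len({c.service_date for c in med} | {c.fill_date for c in rx})
        nominal = sum(c.paid_amount for c in med) + sum(c.paid_amount for c in rx)
        adjusted = sum(
            adjust_to_2021(c.paid_amount, c.service_date.year, cpi_table) for c in med
        ) + sum(adjust_to_2021(c.paid_amount, c.fill_date.year, cpi_table) for c in rx)
        if visits:
            records.append(
                UtilizationRecord(episode.episode_id, category, True, visits, 0, nominal, adjusted)
            )
    return records


def attribute_all(
    episodes,
    dataset: ClaimsDataset,
    codesets: CodeSets,
    cpi_table: dict[int, float],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Utilization records for every episode as a tidy DataFrame.

    Postcondition (checked): every episode has at least one FN-related
    visit — its index-date claim carries an FN-defining diagnosis.
    """
    rows = []
    for ep in episodes:
        recs = attribute_claims(ep, dataset, codesets, cpi_table, config)
        if not any(r.fn_related and r.visit_count > 0 for r in recs):
            raise AssertionError(f"episode {ep.episode_id} has no FN-related visit")
        rows.extend(recs)
    return pd.DataFrame(
        [
            {
                "episode_id": r.episode_id,
                "category": r.category,
                "fn_related": r.fn_related,
                "visit_count": r.visit_count,
                "inpatient_los_days": r.inpatient_los_days,
                "cost_nominal": r.cost_nominal,
                "cost_2021": r.cost_2021,
            }
            for r in rows
        ],
        columns=["episode_id", "category", "fn_related", "visit_count",
                 "inpatient_los_days", "cost_nominal", "cost_2021"],
    )


def episode_totals(util: pd.DataFrame) -> pd.DataFrame:
    """Per-episode total cost (2021 USD), all-cause and FN-related.

    The FN treatment categories (gcsf, antimicrobial) are already counted
    inside the pharmacy/medical FN-related buckets and are excluded from
    the totals to avoid double counting.
    """
    base = util[util["category"].isin(CATEGORIES)]
    totals = (
        base.groupby(["episode_id", "fn_related"])["cost_2021"].sum().unstack(fill_value=0.0)
    )
    totals = totals.rename(columns={False: "all_cause_total", True: "fn_related_total"})
    for col in ("all_cause_total", "fn_related_total"):
        if col not in totals:
            totals[col] = 0.0
    return totals.reset_index()


def _stats(values: np.ndarray) -> dict:
    if values.size == 0:
        return {"mean": None, "sd": None, "median": None}
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else None,
        "median": float(np.median(values)),
    }


def summarize_costs(
    util: pd.DataFrame,
    strata: dict[str, list[str]],
) -> pd.DataFrame:
    """Per stratum x category x (all-cause | FN-related) cost/visit summary.

    ``strata`` maps a stratum label to its episode ids.  Cost statistics
    are computed among episodes with at least one claim in the category
    (zero-use episodes are excluded from that category's mean); mean LOS is
    among episodes contributing inpatient days.
    """
    rows = []
    for label, episode_ids in strata.items():
        ids = set(episode_ids)
        sub = util[util["episode_id"].isin(ids)]
        for category in CATEGORIES + TREATMENT_CATEGORIES:
            for fn_related in (False, True):
                if category in TREATMENT_CATEGORIES and not fn_related:
                    continue
                block = sub[(sub["category"] == category) & (sub["fn_related"] == fn_related)]
                users = block[(block["visit_count"] > 0) | (block["cost_2021"] > 0)]
                costs = users["cost_2021"].to_numpy(dtype=float)
                visits = users["visit_count"].to_numpy(dtype=float)
                cost_stats = _stats(costs)
                visit_stats = _stats(visits)
                los = users.loc[users["inpatient_los_days"] > 0, "inpatient_los_days"]
                rows.append(
                    {
                        "stratum": label,
                        "n_episodes": len(ids),
                        "category": category,
                        "fn_related": fn_related,
                        "n_with_use": int(len(users)),
                        "cost_mean": cost_stats["mean"],
                        "cost_sd": cost_stats["sd"],
                        "cost_median": cost_stats["median"],
                        "visits_mean": visit_stats["mean"],
                        "visits_sd": visit_stats["sd"],
                        "visits_median": visit_stats["median"],
                        "los_mean": float(los.mean()) if len(los) else None,
                    }
                )
    return pd.DataFrame(rows)
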