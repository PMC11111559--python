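"""Stratified cohort report: episode counts, demographics, risk factors,
treatments, and cost summaries, plus the attrition log.

Six stratifications are produced: hospitalization status, index year,
hematologic malignancy (composite and individual sites), solid tumor
(composite and individual sites), comorbidity-score category, and age
category.  Malignancy strata may overlap (an episode can carry several
cancer sites); the other four partition the cohort, so their counts sum to
the total and their percentages to 100% up to rounding.  Percentages are
rendered half-up to one decimal; the JSON bundle keeps raw values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from .episode_builder import AttritionLog, FNEpisode
from .hcru_costing import summarize_costs

PARTITION_STRATIFICATIONS = ("episode_type", "index_year", "nci_category", "age_category")
OVERLAP_STRATIFICATIONS = ("hematologic_malignancy", "solid_tumor")

_HEME_GROUPS = ("NHL", "CLL", "other_hematologic")
_SOLID_GROUPS = ("breast", "lung", "colorectal", "prostate", "other_solid")

RISK_FACTOR_COLUMNS = ("rf_older_age_ge65", "rf_bone_metastasis", "rf_surgery",
                       "rf_radiation", "rf_severe_liver_dysfunction", "rf_kidney_dysfunction")

TREATMENT_COLUMNS = (
    "gcsf_any", "gcsf_prophylactic", "gcsf_treatment",
    "gcsf_long_prophylactic", "gcsf_short_prophylactic",
    "gcsf_long_treatment", "gcsf_short_treatment",
    "antimicrobial_any", "antimicrobial_prophylactic", "antimicrobial_treatment",
)


def percent(numerator: int, denominator: int) -> tuple[float | None, str]:
    """Percentage value and its half-up one-decimal rendering.

    A zero denominator yields (None, "NA") rather than a number.
    """
    if denominator == 0:
        return None, "NA"
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    value = 100.0 * numerator / denominator
    rendered = Decimal(100 * numerator) / Decimal(denominator)
    return value, f"{rendered.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def stratify(classifications: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """Episode-id lists per stratum for the six stratifications.

    Raises when an episode cannot be placed in one of the partition
    stratifications.
    """
    out: dict[str, dict[str, list[str]]] = {}

    def partition(name: str, key):
        groups: dict[str, list[str]] = {}
        for _, row in classifications.iterrows():
            label = key(row)
            if label is None:
                raise ValueError(f"episode {row['episode_id']} unassignable in {name}")
            groups.setdefault(label, []).append(row["episode_id"])
        out[name] = dict(sorted(groups.items()))

    partition("episode_type",
              lambda r: "with_hospitalization" if r["has_hospitalization"] else "without_hospitalization")
    partition("index_year", lambda r: str(int(r["index_year"])))
    partition("nci_category", lambda r: r["nci_category"] or None)
    partition("age_category", lambda r: r["age_category"] or None)

    heme: dict[str, list[str]] = {"any_hematologic": []}
    for g in _HEME_GROUPS:
        heme[g] = classifications.loc[classifications[f"cancer_{g}"], "episode_id"].tolist()
    any_heme = classifications[[f"cancer_{g}" for g in _HEME_GROUPS]].any(axis=1)
    heme["any_hematologic"] = classifications.loc[any_heme, "episode_id"].tolist()
    out["hematologic_malignancy"] = heme

    solid: dict[str, list[str]] = {}
    any_solid = classifications[[f"cancer_{g}" for g in _SOLID_GROUPS]].any(axis=1)
    solid["any_solid"] = classifications.loc[any_solid, "episode_id"].tolist()
    for g in _SOLID_GROUPS:
        solid[g] = classifications.loc[classifications[f"cancer_{g}"], "episode_id"].tolist()
    out["solid_tumor"] = solid

    return out


@dataclass
class CohortReport:
    n_episodes: int
    n_patients: int
    n_multi_episode_patients: int
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    attrition: AttritionLog
    strata: dict = field(default_factory=dict)


def _continuous_stats(values: pd.Series) -> dict:
    arr = values.to_numpy(dtype=float)
    if arr.size == 0:
        return {"mean": None, "sd": None, "median": None, "min": None, "max": None}
    return {
        "mean": float(np.mean(arr)),
        "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else None,
        "median": float(np.median(arr)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
    }


def build_report(
    episodes: list[FNEpisode],
    classifications: pd.DataFrame,
    util: pd.DataFrame,
    attrition: AttritionLog,
) -> CohortReport:
    n_total = len(classifications)
    strata = stratify(classifications) if n_total else {
        name: {} for name in PARTITION_STRATIFICATIONS + OVERLAP_STRATIFICATIONS
    }

    # table 1: episode counts per stratum
    rows1 = []
    for name, groups in strata.items():
        for label, ids in groups.items():
            value, rendered = percent(len(ids), n_total) if n_total else (None, "NA")
            rows1.append({"stratification": name, "stratum": label,
                          "n_episodes": len(ids), "pct": value, "pct_rendered": rendered})
    table1 = pd.DataFrame(rows1, columns=["stratification", "stratum", "n_episodes",
                                          "pct", "pct_rendered"])

    # table 2: demographics for overall + hospitalization strata
    rows2 = []
    demo_strata = {"all": classifications} if n_total else {}
    for label, ids in strata.get("episode_type", {}).items():
        demo_strata[label] = classifications[classifications["episode_id"].isin(set(ids))]
    for label, sub in demo_strata.items():
        n = len(sub)
        for var, stats in (("age_years", _continuous_stats(sub["age_years"])) ,
                           ("episode_length_days", _continuous_stats(sub["episode_length_days"])),
                           ("nci_cci_score", _continuous_stats(sub["nci_cci_score"]))):
            for stat, value in stats.items():
                rows2.append({"stratum": label, "variable": var, "stat": stat,
                              "n": None, "pct": None, "value": value})
        for var, values in (("sex", ("male", "female")),
                            ("payer", ("commercial", "medicare", "medicaid", "unknown")),
                            ("region", ("northeast", "midwest", "south", "west", "unknown"))):
            for level in values:
                count = int((sub[var] == level).sum())
                value, _ = percent(count, n) if n else (None, "NA")
                rows2.append({"stratum": label, "variable": var, "stat": level,
                              "n": count, "pct": value, "value": None})
    table2 = pd.DataFrame(rows2, columns=["stratum", "variable", "stat", "n", "pct", "value"])

    by_id = classifications.set_index("episode_id") if n_total else classifications

    def counts_table(columns) -> pd.DataFrame:
        rows = []
        for name, groups in strata.items():
            for label, ids in groups.items():
                sub = by_id.loc[by_id.index.intersection(ids)] if n_total else by_id
                n = len(ids)
                for col in columns:
                    count = int(sub[col].sum()) if n else 0
                    value, rendered = percent(count, n) if n else (None, "NA")
                    rows.append({"stratification": name, "stratum": label,
                                 "n_episodes": n, "variable": col, "n": count,
                                 "pct": value, "pct_rendered": rendered})
        return pd.DataFrame(rows, columns=["stratification", "stratum", "n_episodes",
                                           "variable", "n", "pct", "pct_rendered"])

    table3 = counts_table(RISK_FACTOR_COLUMNS)

    # chemo risk is categorical: expand to indicator columns first
    risk_cols = []
    for level in ("high", "intermediate", "low_undefined"):
        col = f"chemo_risk_{level}"
        if n_total:
            by_id[col] = by_id["chemo_risk"] == level
        risk_cols.append(col)
    table4 = counts_table(tuple(risk_cols) + TREATMENT_COLUMNS) if n_total else counts_table(())

    flat_strata = {"all": classifications["episode_id"].tolist() if n_total else []}
    for name, groups in strata.items():
        for label, ids in groups.items():
            flat_strata[f"{name}:{label}"] = ids
    table5 = summarize_costs(util, flat_strata) if len(util) else pd.DataFrame(
        columns=["stratum", "n_episodes", "category", "fn_related", "n_with_use",
                 "cost_mean", "cost_sd", "cost_median", "visits_mean", "visits_sd",
                 "visits_median", "los_mean"])

    members = {e.member_id for e in episodes}
    per_member = pd.Series([e.member_id for e in episodes]).value_counts() if episodes else pd.Series(dtype=int)

    return CohortReport(
        n_episodes=n_total,
        n_patients=len(members),
        n_multi_episode_patients=int((per_member > 1).sum()) if episodes else 0,
        table1=table1,
        table2=table2,
        table3=table3,
        table4=table4,
        table5=table5,
        attrition=attrition,
        strata=strata,
    )


def render_report(report: CohortReport, out_dir: str | Path) -> dict[str, Path]:
    """Write one CSV per table plus a raw-value JSON bundle.

    Human-readable CSVs format counts with thousands separators; the JSON
    keeps unrounded numerators, denominators, and percentage values so
    every printed percentage is re-derivable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, table in [("table1_episode_counts", report.table1),
                        ("table2_demographics", report.table2),
                        ("table3_risk_factors", report.table3),
                        ("table4_treatments", report.table4),
                        ("table5_hcru_costs", report.table5)]:
        human = table.copy()
        for col in ("n_episodes", "n"):
            if col in human.columns:
                human[col] = human[col].map(
                    lambda v: f"{int(v):,}" if pd.notna(v) and v is not None else "")
        path = out / f"{name}.csv"
        human.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
        paths[name] = path

    def records(df: pd.DataFrame, drop=()) -> list[dict]:
        df = df.drop(columns=[c for c in drop if c in df.columns])
        return [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in df.to_dict(orient="records")
        ]

    bundle = {
        "n_episodes": report.n_episodes,
        "n_patients": report.n_patients,
        "n_multi_episode_patients": report.n_multi_episode_patients,
        "attrition": [{"criterion": c, "remaining": n} for c, n in report.attrition.steps],
        "table1": records(report.table1, drop=["pct_rendered"]),
        "table3": records(report.table3, drop=["pct_rendered"]),
        "table4": records(report.table4, drop=["pct_rendered"]),
        "table5": records(report.table5),
    }
    json_path = out / "report.json"

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"unserializable {type(o)}")

    json_path.write_text(json.dumps(bundle, indent=1, default=default,
                                    allow_nan=False) + "\n")
    paths["report_json"] = json_path
    return paths
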