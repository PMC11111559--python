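"""Attribute utilization and cost to episodes and summarize by stratum.

Every claim dated inside an episode is bucketed by care setting, once
all-cause and once FN-related (claims carrying a neutropenia / infection /
fever diagnosis, or GCSF / antimicrobial claims).  Costs are converted to
2021 USD with the medical-CPI table before averaging; category means are
taken among episodes with at least one claim in the category.
"""

from fnepisodes import (GeneratorConfig, attribute_all, build_cohort,
                        classify_episodes, episode_totals,
                        generate_synthetic_claims, load_codesets,
                        load_cpi_table, summarize_costs, stratify)

dataset, _ = generate_synthetic_claims(GeneratorConfig(n_members=600, seed=11))
codesets = load_codesets()
cpi = load_cpi_table()

episodes, _ = build_cohort(dataset, codesets)
cls = classify_episodes(episodes, dataset, codesets)
util = attribute_all(episodes, dataset, codesets, cpi)
totals = episode_totals(util)

hosp_ids = {e.episode_id for e in episodes if e.has_hospitalization}
fn = totals.set_index("episode_id")["fn_related_total"]
print(f"{len(episodes)} episodes "
      f"({100 * len(hosp_ids) / len(episodes):.1f}% with hospitalization)")
print(f"  mean FN-related cost, all episodes:      ${fn.mean():>9,.0f}")
print(f"  ... with hospitalization:                ${fn[fn.index.isin(hosp_ids)].mean():>9,.0f}")
print(f"  ... without hospitalization:             ${fn[~fn.index.isin(hosp_ids)].mean():>9,.0f}")

summary = summarize_costs(util, {"all": [e.episode_id for e in episodes]})
row = summary[(summary["category"] == "inpatient") & summary["fn_related"]].iloc[0]
print(f"  FN-related inpatient: n with use {row['n_with_use']}, "
      f"mean cost ${row['cost_mean']:,.0f}, mean LOS {row['los_mean']:.1f} days")
print("Costs are 2021 USD; FN-related cost is always <= all-cause cost for "
      "an episode because FN-related claims are a subset of all claims.")
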