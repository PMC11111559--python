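"""Classify each episode's chemotherapy FN-risk and GCSF/antimicrobial use.

Prophylactic use means a fill on the date of, or within 4 days after, the
first chemotherapy administration of the 30-day treatment window; any
later use in the window counts as treatment.  The two are not mutually
exclusive.
"""

from fnepisodes import (GeneratorConfig, build_cohort, classify_episodes,
                        generate_synthetic_claims, load_codesets)

dataset, _ = generate_synthetic_claims(GeneratorConfig(n_members=400, seed=7))
codesets = load_codesets()
episodes, _ = build_cohort(dataset, codesets)
cls = classify_episodes(episodes, dataset, codesets)

n = len(cls)
print(f"{n} episodes")
for level in ("high", "intermediate", "low_undefined"):
    share = 100 * (cls["chemo_risk"] == level).mean()
    print(f"  chemo FN-risk {level:<14} {share:5.1f}%")
users = cls["gcsf_any"]
print(f"  GCSF use (any)           {100 * users.mean():5.1f}%")
print(f"    prophylactic | users   {100 * cls.loc[users, 'gcsf_prophylactic'].mean():5.1f}%")
print(f"    treatment    | users   {100 * cls.loc[users, 'gcsf_treatment'].mean():5.1f}%")
print(f"  antimicrobial use (any)  {100 * cls['antimicrobial_any'].mean():5.1f}%")
print("Shares describe the 30-day pre-index chemotherapy treatment period; "
      "prophylactic and treatment GCSF can both be true for one episode.")
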