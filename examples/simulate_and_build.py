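"""Generate a synthetic claims cohort and build FN episodes from it.

The generator plants episode intents (plus a few members with deliberate
qualification violations); the episode builder must recover exactly the
valid ones.  The attrition log shows how many candidates each study
criterion removed.
"""

from fnepisodes import GeneratorConfig, build_cohort, generate_synthetic_claims, load_codesets

config = GeneratorConfig(n_members=150, n_violation_members=21, seed=42)
dataset, ledger = generate_synthetic_claims(config)
codesets = load_codesets()

episodes, attrition = build_cohort(dataset, codesets)

print(f"claims: {len(dataset.medical)} medical, {len(dataset.pharmacy)} pharmacy, "
      f"{len(dataset.members)} members")
for criterion, remaining in attrition.steps:
    print(f"  {criterion:<32} {remaining}")

planted = sum(1 for e in ledger if e.violation is None)
print(f"episodes retained: {len(episodes)} (generator planted {planted} valid)")
print("Each attrition row is the number of candidate index events still "
      "eligible after that criterion; the final row is the episode count.")
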