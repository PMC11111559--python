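# Methods

This note documents the episode model, the interpretation choices the
implementation makes where the underlying study design is ambiguous, what
the synthetic-claims generator does and does not emulate, and the known
limitations.

## Episode model

An FN episode is a bounded window anchored at an index date — the first
date on which the case definition fires — with three derived windows:

| window | interval | used for |
|---|---|---|
| pre-episode | `[index−180, index−1]` | enrollment continuity, clean period, comorbidities, risk factors, cancer sites, exclusions |
| chemotherapy treatment | `[index−30, index−1]` | episode qualification, regimen FN-risk, GCSF/antimicrobial classification |
| episode | `[index, end]` | utilization and cost attribution |

All dates are whole calendar days and all intervals are closed on both
ends. Episode length is counted inclusively, `end − index + 1`, so a
capped episode without hospitalization has length 61; the shortest
reachable length under the "next incident chemotherapy strictly after
index" termination rule is 2 days. Termination takes the earlier of the
next chemotherapy date and `index+60`; an FN-related inpatient stay
admitted inside that provisional window whose discharge runs later
extends the episode to the discharge date — the only way lengths can
exceed 61 days.

Diagnosis evidence for the case definition is pooled across same-date
claims of the qualifying setting class (all inpatient claims of the date,
or all outpatient claims of the date); the `require_same_claim_dx` switch
restricts it to a single claim carrying both diagnoses. When both the
inpatient and the outpatient arm fire on one date, the candidate is
labelled inpatient — a deterministic tie-break; hospitalization status is
computed independently from the episode's claims, so the label has no
downstream effect on stratification.

### Subsequent episodes

The clean-pre-period criterion (no neutropenia/infection/fever diagnosis
in the prior 180 days) cannot hold verbatim for a member's second episode
— the first episode's own index claims sit in that window — yet
multi-episode members exist by design. The implementation therefore
applies the full 180-day clean-period rule to a member's first episode
only; later candidates are governed by the washout rule: at least 30
consecutive diagnosis-free days strictly between the previously retained
episode's end and the new index. `subsequent_episode_rule =
"full_clean_period"` restores the strict reading (under which virtually
no member can have two episodes).

Other interpretation switches, each defaulting to the reading we judged
most faithful: chemotherapy on the index date neither qualifies the
episode (`chemo_window_includes_index=False`) nor terminates it
(termination uses chemotherapy strictly after index); the COVID-19
exclusion covers the pre-episode window and the index date; comorbidity
and risk-factor lookback excludes the index date, consistent with the
clean-period convention.

## Classification

Chemotherapy regimens are configuration objects: a drug-code set that
must be fully evidenced in the treatment window, an FN-risk label, an
optional conditional diagnosis requirement (for context-dependent agents
such as docetaxel or topotecan), and an optional minimum count of
administration dates over the 180-day lookback (cycle-count conditions
for doxorubicin/cyclophosphamide). An episode takes the highest risk
among matched regimens; no match means low/undefined.

Prophylaxis is anchored at the first chemotherapy administration in the
treatment window: use on day 0 through day +4 is prophylactic, any later
use in the window is treatment, and one episode can be both. GCSF codes
are split short-acting (filgrastim-class) vs long-acting
(pegfilgrastim-class) in the codeset registry.

The comorbidity score is a weight sum over configured condition
categories, each counted once if any of its diagnosis codes appears in
the lookback. The shipped weights are integer Charlson-style defaults;
the published NCI adaptation carries non-integer weights and can be
dropped in as configuration — the scoring algorithm is agnostic. Score
categories are 0, >0–<2, and ≥2, the only partition consistent with the
three-way split the algorithm is meant to report.

Inpatient "visits" are maximal unions of overlapping admission spans
(claims data routinely split one stay across rows); length of stay
defaults to `discharge − admission + 1` with a minimum of 1
(`los_convention="difference"` gives the uncounted-discharge-day
variant). Outpatient visit counts are distinct service dates per
category; pharmacy counts are fills.

## Synthetic generator

The generator is the package's stand-in for a claims warehouse. Its
defaults encode the study conditions the pipeline is meant to operate
under: 91% of episodes hospitalized; chemotherapy FN-risk mix
19.7 / 49.4 / 30.9 percent (high / intermediate / low-undefined); GCSF use
in 40% of episodes, 67.2% of users prophylactic and 58.4% treatment (not
mutually exclusive; long-acting shares 92.8% and 76.9% respectively);
antimicrobial use in 24.1% (28.4% / 79.3%); risk-factor prevalences
(surgery 0.86, radiation 0.24, bone metastasis 0.17, kidney dysfunction
0.142, severe liver dysfunction 0.033); 2.9% of members with a second
episode; age ~ Normal(55.4, 15), 60.6% female, payer and region mixes to
match. FN-related episode cost is lognormal, moment-matched
(`sdlog² = ln(1+(sd/mean)²)`, `meanlog = ln(mean) − sdlog²/2`) to mean
$26,868 / SD $41,183 for hospitalized and $7,738 / $15,030 for
non-hospitalized episodes, in 2021 USD; claims are written in nominal
dollars of the service year using the same CPI table the pipeline uses to
re-inflate, so planted costs round-trip exactly (to the cent). Non-FN
"background" utilization adds a lognormal mean $10,723 / SD $15,000 of
all-cause-only cost spread over office, other-outpatient, and pharmacy
claims. Episode termination structure: 85% of episodes have a next
chemotherapy 7–45 days after index, the rest run to the 60-day cap;
hospitalized index stays draw a lognormal length of stay matched to mean
6.9 / SD 7.2 days.

Every planted episode is recorded in a ground-truth ledger — index date,
expected end, hospitalization, costs, treatment flags and timing,
comorbidity score, risk factors, cancer sites — and violation members are
planted with exactly one qualification defect and its expected rejection
label. Tests treat the ledger, never the claims, as the oracle.

What the generator does **not** emulate: real code frequencies and coding
noise (each clinical fact is planted as a single clean code), seasonal or
regional utilization patterns, correlated comorbidity structure,
per-category cost composition beyond the FN/non-FN split, and episode
lengths' empirical shape (the uniform next-chemotherapy gap reproduces
the mean, not the skew, of observed lengths). Passing tests therefore
demonstrate algorithmic correctness under the stated statistical
structure, not performance characteristics (sensitivity/specificity) on
real claims.

## Numerical choices

* Percentages render half-up to one decimal via exact decimal arithmetic;
  raw values are kept alongside in JSON output.
* Standard deviations are sample (n−1) throughout; single-observation
  groups report a null SD.
* Category cost statistics are computed among episodes with ≥1 claim in
  the category; empty strata report null statistics rather than zeros.
* Inflation uses annual medical-CPI index values (`cost_2021 =
  cost × index₂₀₂₁ / index_year`); no month-level adjustment.
* Attrition is counted over candidates surviving each criterion in the
  fixed evaluation order, so the log is reproducible and non-increasing
  by construction.
* Ages derive from birth year only (`index.year − birth_year`), the
  resolution claims extracts typically provide.

## Problem sizes

The default test suite runs in well under a minute: oracle-equivalence
checks use datasets of ≤10 members against a deliberately naive
day-by-day reference implementation; statistical recovery checks use
2,000–5,000 planted episodes (binomial/SE bounds at 3 standard errors);
invariant sweeps use 20 seeds of ~37-member cohorts. The acceptance
script uses a 5,000-member cohort, chosen so sampling error on recovered
shares is a few tenths of a percentage point while the full pipeline
completes in seconds.

## Known limitations

* Codeset defaults are placeholders, not validated code lists; any real
  analysis must supply its own registry (and the algorithm's fidelity is
  then bounded by that registry's quality).
* Claim settings come from an explicit `setting` column; mapping from
  place-of-service/revenue codes is out of scope.
* No probabilistic phenotyping and no chart-review validation metrics;
  the pipeline is deterministic rule evaluation.
* Costs are a single paid-amount field; payer/patient decomposition is
  not modelled.
* ICD-9-era data is unsupported (the design targets an ICD-10 window).
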