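# Default codeset registry.
#
# These are PLACEHOLDER code lists: plausible ICD-10-CM diagnosis codes,
# HCPCS-style procedure/J-codes, and symbolic pharmacy drug tokens chosen so
# the pipeline is runnable and testable out of the box.  A production
# deployment replaces every list here with the code lists of its own data
# source (real NDCs, full ICD-10-CM ranges, plan-specific HCPCS).  The
# algorithms never hard-code a code: they see only these named sets.

codesets:
  neutropenia_dx:
    system: ICD-10-CM
    codes: [D70.1, D70.2, D70.8, D70.9]
  fever_dx:
    system: ICD-10-CM
    codes: [R50.81, R50.9]
  bacterial_infection_dx:
    system: ICD-10-CM
    codes: [A41.9, A49.9, J15.9, N39.0]
  fungal_infection_dx:
    system: ICD-10-CM
    codes: [B37.0, B37.7, B44.9]
  covid_dx:
    system: ICD-10-CM
    codes: [U07.1]
  excluded_heme_dx:        # ALL, AML, CML, MDS
    system: ICD-10-CM
    codes: [C91.00, C91.01, C92.00, C92.01, C92.10, D46.9]
  bmt_sct_cart_proc:       # bone marrow / stem cell transplant, CAR-T
    system: HCPCS
    codes: ["38240", "38241", Q2041, Q2042, XW033C3]
  bone_met_dx:
    system: ICD-10-CM
    codes: [C79.51]
  surgery_proc:
    system: CPT/HCPCS
    codes: ["19303", "32480", "44140", "60220"]
  radiation_codes:
    system: CPT + ICD-10-CM
    codes: ["77401", "77402", "77407", "77412", Z51.0]
  liver_dysfunction_dx:
    system: ICD-10-CM
    codes: [K70.40, K72.90, K72.91]
  kidney_dysfunction_dx:
    system: ICD-10-CM
    codes: [N17.9, N18.4, N18.5, N18.6]

  gcsf_short:              # filgrastim-class (daily)
    system: HCPCS
    codes: [J1442, J1447, Q5101, Q5110]
  gcsf_long:               # pegfilgrastim-class (once per cycle)
    system: HCPCS
    codes: [J2505, Q5108, Q5111, Q5122]

  # oral antibiotic agents used by the outpatient FN definition; drug codes
  # are symbolic placeholder tokens standing in for NDC lists.
  abx_ciprofloxacin:
    system: NDC-placeholder
    codes: [CIP250, CIP500]
  abx_amox_clav:
    system: NDC-placeholder
    codes: [AMC500, AMC875]
  abx_clindamycin:
    system: NDC-placeholder
    codes: [CLD150, CLD300]
  abx_levofloxacin:
    system: NDC-placeholder
    codes: [LVX500, LVX750]
  abx_moxifloxacin:
    system: NDC-placeholder
    codes: [MXF400]

  nccn_parenteral_antibiotic_proc:
    system: HCPCS
    codes: [J0690, J0696, J1956, J2543]

  antibacterial:
    system: NDC-placeholder
    codes: [CIP250, CIP500, AMC500, AMC875, CLD150, CLD300, LVX500, LVX750,
            MXF400, AZM250, SXT800]
  antifungal:
    system: NDC-placeholder
    codes: [FLU150, VOR200]
  antiviral:
    system: NDC-placeholder
    codes: [ACV400, VAL500]

  # cancer-site diagnosis groups
  nhl_dx:
    system: ICD-10-CM
    codes: [C82.90, C83.30, C85.90]
  cll_dx:
    system: ICD-10-CM
    codes: [C91.10, C91.11]
  other_hematologic_dx:    # e.g. Hodgkin lymphoma, histiocytosis, mastocytosis
    system: ICD-10-CM
    codes: [C81.90, C96.0, C96.20]
  breast_dx:
    system: ICD-10-CM
    codes: [C50.911, C50.912, C50.919]
  lung_dx:
    system: ICD-10-CM
    codes: [C34.90, C34.91, C34.92]
  colorectal_dx:
    system: ICD-10-CM
    codes: [C18.9, C19, C20]
  prostate_dx:
    system: ICD-10-CM
    codes: [C61]
  other_solid_dx:
    system: ICD-10-CM
    codes: [C25.9, C56.9, C67.9]

# oral regimens accepted as NCCN-recommended antibiotic evidence for the
# outpatient definition; each inner list names agent codesets that must ALL
# be filled on the candidate date.
oral_antibiotic_combinations:
  - [abx_ciprofloxacin, abx_amox_clav]
  - [abx_ciprofloxacin, abx_clindamycin]
  - [abx_levofloxacin]
  - [abx_moxifloxacin]

# chemotherapy regimens with NCCN FN-risk labels.  Drug codes are HCPCS
# J-codes for physician-administered agents.  requires_dx: the regimen only
# matches when the named dx set is evidenced in the pre-episode window
# (context-dependent agents).  min_admin_count: distinct administration
# dates required over the 180-day lookback (cycle-count conditions).
regimens:
  - name: TAC                      # docetaxel + doxorubicin + cyclophosphamide
    risk: high
    drugs: [J9171, J9000, J9070]
    requires_dx: breast_dx
  - name: dose_dense_AC            # doxorubicin + cyclophosphamide, q2w cycles
    risk: high
    drugs: [J9000, J9070]
    min_admin_count: 2
  - name: CHOP
    risk: intermediate
    drugs: [J9000, J9070, J9370]
  - name: carboplatin_paclitaxel
    risk: intermediate
    drugs: [J9045, J9267]
  - name: topotecan_mono
    risk: intermediate
    drugs: [J9351]
    requires_dx: lung_dx
  - name: gemcitabine_mono
    risk: low_undefined
    drugs: [J9201]
  - name: fluorouracil_mono
    risk: low_undefined
    drugs: [J9190]

# Charlson-style comorbidity conditions with integer default weights.
# Replace with the NCI comorbidity-index condition map (which carries
# non-integer weights) to reproduce a specific published adaptation; the
# scoring algorithm is a weight sum over conditions evidenced in the
# pre-episode window and is agnostic to the weights used.
cci_conditions:
  myocardial_infarction: {weight: 1, codes: [I21.9, I25.2]}
  congestive_heart_failure: {weight: 1, codes: [I50.9]}
  peripheral_vascular_disease: {weight: 1, codes: [I73.9]}
  cerebrovascular_disease: {weight: 1, codes: [I63.9]}
  dementia: {weight: 1, codes: [F03.90]}
  copd: {weight: 1, codes: [J44.9]}
  rheumatic_disease: {weight: 1, codes: [M05.9]}
  peptic_ulcer_disease: {weight: 1, codes: [K27.9]}
  mild_liver_disease: {weight: 1, codes: [K76.0]}
  diabetes: {weight: 1, codes: [E11.9]}
  diabetes_with_complications: {weight: 2, codes: [E11.21, E11.22]}
  hemiplegia: {weight: 2, codes: [G81.90]}
  renal_disease: {weight: 2, codes: [N18.4, N18.5, N18.6]}
  aids: {weight: 6, codes: [B20]}
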