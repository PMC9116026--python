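genes:
- gene: ATM
  categories:
  - label: outside_FAT_PIK
    n_variants: 714
    alpha: 0.0041
    template:
      domain:
      - none
  - label: FAT_PIK_CADD1-4
    n_variants: 171
    alpha: 0.055
    template:
      domain:
      - FAT
      - PIK
      cadd:
      - 0.0
      - 3.736542
  - label: FAT_PIK_CADD5
    n_variants: 103
    alpha: 0.54
    template:
      domain:
      - FAT
      - PIK
      cadd:
      - 3.736542
      - 12.0
  or_missense: 2.16
  or_ptv: 2.16
  ptv_carrier_freq: 0.0034
  freq_dist:
  - 2.0e-06
  - 0.0001
- gene: BRCA1
  categories:
  - label: outside_RING_BRCT
    n_variants: 479
    alpha: 0.0015
    template:
      domain:
      - none
  - label: RING_BRCT_Helix-low
    n_variants: 79
    alpha: 1.0e-11
    template:
      domain:
      - RING
      - BRCT
      helix:
      - 0.0
      - 0.5
  - label: RING_BRCT_Helix-high
    n_variants: 23
    alpha: 0.48
    template:
      domain:
      - RING
      - BRCT
      helix:
      - 0.5
      - 1.0
  or_missense: 10.61
  or_ptv: 10.61
  ptv_carrier_freq: 0.00144
  freq_dist:
  - 2.0e-06
  - 0.0001
- gene: BRCA2
  categories:
  - label: Helix-low
    n_variants: 1160
    alpha: 5.1e-05
    template:
      helix:
      - 0.0
      - 0.5
  - label: Helix-high
    n_variants: 62
    alpha: 0.11
    template:
      helix:
      - 0.5
      - 1.0
  or_missense: 5.87
  or_ptv: 5.87
  ptv_carrier_freq: 0.0031
  freq_dist:
  - 2.0e-06
  - 0.0001
- gene: CHEK2
  categories:
  - label: Helix-low
    n_variants: 157
    alpha: 0.33
    template:
      helix:
      - 0.0
      - 0.5
  - label: Helix-high
    n_variants: 121
    alpha: 0.95
    template:
      helix:
      - 0.5
      - 1.0
  or_missense: 1.75
  or_ptv: 2.54
  ptv_carrier_freq: 0.0031
  freq_dist:
  - 2.0e-06
  - 0.0001
- gene: PALB2
  categories:
  - label: carriers
    n_variants: 424
    alpha: 0.00011
    template: {}
  or_missense: 4.87
  or_ptv: 4.87
  ptv_carrier_freq: 0.0013
  freq_dist:
  - 2.0e-06
  - 0.0001
strata:
- label: UK
  baseline_logodds: -2.2
  n_subjects: 150000
  design: population
- label: DE
  baseline_logodds: -2.25
  n_subjects: 90000
  design: population
- label: DK
  baseline_logodds: -2.15
  n_subjects: 60000
  design: population
- label: SE
  baseline_logodds: -2.3
  n_subjects: 60000
  design: population
- label: FR-FAM
  baseline_logodds: -2.25
  n_subjects: 40000
  design: familial
target_cases: 35000
target_controls: 38000
familial_oversample: 2.0
splice_excluded_rate: 0.0
seed: 20220518
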