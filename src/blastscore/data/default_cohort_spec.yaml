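# Default synthetic-cohort specification.
#
# Prevalences are the marginal frequencies of each diagnostic group in the
# validation cohort (121 blastoid HGBL vs 47 B-ALL): flow criteria from the
# immunophenotype comparison table, genetic flags from the cytogenetic /
# mutation comparison table.  The Bernoulli "1" state is always the
# HGBL-typical state for criterion features.
#
# atypical_fraction: fraction of each group's cases whose swap_features are
# drawn from the opposite group's prevalences (aberrant-immunophenotype
# mimics).  The default of 0 generates pure marginal cohorts.

n_hgbl: 121
n_ball: 47
seed: 0

prevalence:
  HGBL:
    cd45_gt_granulocytes: 0.75   # CD45 intensity > granulocytes, 72/96
    cd10_not_bright: 0.86        # CD10 below hematogone level, 83/96
    cd20_ge_mature_b: 0.72       # CD20 >= mature B cells, 47/65
    cd38_bright: 0.70            # CD38 at hematogone level, 67/96
    tdt_negative: 0.83           # TdT negative, either modality, 72/87
    myc_pos_or_r: 0.84           # MYC IHC >=40% and/or MYC-R
    bcl6_pos: 0.77               # BCL6 IHC >=30%, 84/109
    cd34_pos: 0.0                # 0/96
    myeloid_pos: 0.0             # 0/30
    slc_monotypic: 0.75          # 72/96
    bcl2_pos: 0.85               # BCL2 IHC >=50%, 98/115
    myc_r: 0.72                  # 87/121
    complex_karyotype: 0.93      # 53/57
    ball_translocation: 0.0      # 0/57
    tp53_mut: 0.44               # 11/25
    kras_mut: 0.0                # 0/25
    nras_mut: 0.0                # 0/25
    history_nhl: 0.33            # 40/121
  BALL:
    cd45_gt_granulocytes: 0.23   # 11/47
    cd10_not_bright: 0.58        # 27/47
    cd20_ge_mature_b: 0.11       # 5/46
    cd38_bright: 0.38            # 18/47
    tdt_negative: 0.11           # 5/45
    myc_pos_or_r: 0.20           # 9/46 (MYC IHC only; no B-ALL has MYC-R)
    bcl6_pos: 0.16               # 6/37
    cd34_pos: 0.47               # 22/47
    myeloid_pos: 0.41            # 19/46
    slc_monotypic: 0.0           # 0/5
    bcl2_pos: 1.0                # 7/7
    myc_r: 0.0                   # 0/44
    complex_karyotype: 0.46      # 19/41
    ball_translocation: 0.57     # 27/47
    tp53_mut: 0.15               # 6/41
    kras_mut: 0.17               # 7/41
    nras_mut: 0.22               # 9/41
    history_nhl: 0.0

atypical_fraction:
  HGBL: 0.0
  BALL: 0.0

swap_features:
  - cd45_gt_granulocytes
  - cd10_not_bright
  - cd20_ge_mature_b
  - cd38_bright
  - tdt_negative
  - myc_pos_or_r
  - bcl6_pos
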