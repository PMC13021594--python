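# Synthetic cohort specification: per-sex, per-age-group sizes and
# feature-target means (cy cm, m_my nominal units, zcr_y / zcr_vx counts per
# 12 s, cri_t s, st_n samples). Female group sizes sum to 2,663; the source
# cohort reports one more female in total than its per-group breakdown, a
# discrepancy left as-is here.
groups:
  - {sex: male, age_group: 1, label: "<=69", n: 176,
     targets: {cy: 0.23, m_my: 0.43, zcr_y: 14.8, zcr_vx: 87, cri_t: 1.03, st_n: 141}}
  - {sex: male, age_group: 2, label: "70-74", n: 588,
     targets: {cy: 0.30, m_my: 0.47, zcr_y: 17.7, zcr_vx: 140, cri_t: 0.97, st_n: 81}}
  - {sex: male, age_group: 3, label: "75-79", n: 590,
     targets: {cy: 0.35, m_my: 0.48, zcr_y: 18.7, zcr_vx: 131, cri_t: 0.91, st_n: 83}}
  - {sex: male, age_group: 4, label: "80-84", n: 431,
     targets: {cy: 0.40, m_my: 0.49, zcr_y: 19.7, zcr_vx: 124, cri_t: 0.92, st_n: 82}}
  - {sex: male, age_group: 5, label: ">=85", n: 140,
     targets: {cy: 0.49, m_my: 0.53, zcr_y: 22.1, zcr_vx: 123, cri_t: 0.83, st_n: 66}}
  - {sex: female, age_group: 1, label: "<=69", n: 318,
     targets: {cy: 0.23, m_my: 0.32, zcr_y: 15.7, zcr_vx: 148, cri_t: 1.10, st_n: 225}}
  - {sex: female, age_group: 2, label: "70-74", n: 809,
     targets: {cy: 0.26, m_my: 0.32, zcr_y: 17.3, zcr_vx: 165, cri_t: 1.10, st_n: 183}}
  - {sex: female, age_group: 3, label: "75-79", n: 760,
     targets: {cy: 0.29, m_my: 0.33, zcr_y: 17.7, zcr_vx: 158, cri_t: 1.00, st_n: 182}}
  - {sex: female, age_group: 4, label: "80-84", n: 594,
     targets: {cy: 0.36, m_my: 0.36, zcr_y: 19.4, zcr_vx: 145, cri_t: 0.93, st_n: 162}}
  - {sex: female, age_group: 5, label: ">=85", n: 182,
     targets: {cy: 0.41, m_my: 0.36, zcr_y: 22.1, zcr_vx: 167, cri_t: 0.96, st_n: 146}}
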