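scenarios:
- name: status_quo
- name: s2_denmark
  reductions:
    1: 12.0
    2: 33.0
    4: 24.0
- name: s3_dk_se_de
  reductions:
    1: 33.0
    2: 33.0
    3: 33.0
    4: 33.0
- name: s4_bsap
  reductions:
    1: 9.0
    2: 20.0
    3: 15.0
    4: 32.0
    5: 21.4
    9: 23.0
    12: 19.0
    13: 19.0
    14: 35.0
    17: 33.0
- name: s5_pan_baltic
  reductions: pan_baltic_33
- name: s6_cod_half_f
  F_rule:
    FCD:
    - halve
    - 0.32
- name: s7_sprat_half_f
  F_rule:
    FSR:
    - halve
    - 0.07
- name: s8_cod_double_f
  F:
    FCD: 0.64
- name: s9_sprat_double_f
  F:
    FSR: 0.14
- name: s10_max_f
  F:
    FCD: 1.2
    FSR: 0.6
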