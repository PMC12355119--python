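name: PCS
items:
- pcs_1
- pcs_2
- pcs_3
- pcs_4
- pcs_5
- pcs_6
- pcs_7
- pcs_8
- pcs_9
- pcs_10
- pcs_11
- pcs_12
- pcs_13
min: 0
max: 4
reverse: []
subscales:
  rumination:
  - pcs_8
  - pcs_9
  - pcs_10
  - pcs_11
  magnification:
  - pcs_6
  - pcs_7
  - pcs_13
  helplessness:
  - pcs_1
  - pcs_2
  - pcs_3
  - pcs_4
  - pcs_5
  - pcs_12
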