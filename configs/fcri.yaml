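name: FCRI
items:
- fcri_1
- fcri_2
- fcri_3
- fcri_4
- fcri_5
- fcri_6
- fcri_7
- fcri_8
- fcri_9
- fcri_10
- fcri_11
- fcri_12
- fcri_13
- fcri_14
- fcri_15
- fcri_16
- fcri_17
- fcri_18
- fcri_19
- fcri_20
- fcri_21
- fcri_22
- fcri_23
- fcri_24
- fcri_25
- fcri_26
- fcri_27
- fcri_28
- fcri_29
- fcri_30
- fcri_31
- fcri_32
- fcri_33
- fcri_34
- fcri_35
- fcri_36
- fcri_37
- fcri_38
- fcri_39
- fcri_40
- fcri_41
- fcri_42
min: 0
max: 4
reverse:
- fcri_13
subscales:
  F1_triggers:
  - fcri_1
  - fcri_2
  - fcri_3
  - fcri_4
  - fcri_5
  - fcri_6
  - fcri_7
  - fcri_8
  F2_severity:
  - fcri_9
  - fcri_10
  - fcri_11
  - fcri_12
  - fcri_13
  - fcri_14
  - fcri_15
  - fcri_16
  - fcri_17
  F3_distress:
  - fcri_18
  - fcri_19
  - fcri_20
  - fcri_21
  F4_functioning:
  - fcri_22
  - fcri_23
  - fcri_24
  - fcri_25
  - fcri_26
  - fcri_27
  F5_insight:
  - fcri_28
  - fcri_29
  - fcri_30
  F6_reassurance:
  - fcri_31
  - fcri_32
  - fcri_33
  F7_coping:
  - fcri_34
  - fcri_35
  - fcri_36
  - fcri_37
  - fcri_38
  - fcri_39
  - fcri_40
  - fcri_41
  - fcri_42
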