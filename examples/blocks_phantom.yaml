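reference: phantom-seed0
blocks:
- name: core
  category: core
  selectors:
  - chain: A
    start: 1
    end: 12
- name: CP
  category: CP
  selectors:
  - chain: A
    start: 13
    end: 24
- name: H38
  category: other
  selectors:
  - chain: A
    start: 25
    end: 36
- name: L1_stalk
  category: L1_stalk
  selectors:
  - chain: A
    start: 37
    end: 48
- name: H68
  category: H68_69
  selectors:
  - chain: A
    start: 49
    end: 60
- name: H69
  category: H68_69
  selectors:
  - chain: A
    start: 61
    end: 72
- name: H71
  category: PTC
  selectors:
  - chain: A
    start: 73
    end: 84
- name: H73
  category: PTC
  selectors:
  - chain: A
    start: 85
    end: 96
- name: H89
  category: PTC
  selectors:
  - chain: A
    start: 97
    end: 108
- name: H90_93
  category: PTC
  selectors:
  - chain: A
    start: 109
    end: 120
- name: uL16
  category: protein
  selectors:
  - chain: A
    start: 121
    end: 132
- name: bL33
  category: protein
  selectors:
  - chain: A
    start: 133
    end: 144
- name: bL35
  category: protein
  selectors:
  - chain: A
    start: 145
    end: 156
- name: bL36
  category: protein
  selectors:
  - chain: A
    start: 157
    end: 168
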