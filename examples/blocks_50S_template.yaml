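# Block-library template for a mature E. coli 50S reference (e.g. PDB 7K00).
#
# The residue ranges below are PLACEHOLDERS (start = end = 1): fill them in
# against your own reference model's author numbering before use. A full
# segmentation of the 50S runs to ~114 blocks; this template lists only the
# landmark helices and proteins the maturation-state taxonomy keys on, plus
# the coarse regions. Ranges are inclusive on both ends; chain ids follow
# the reference (23S rRNA is typically one chain, each r-protein its own).
#
# Categories: core, CP, PTC, H68_69, L1_stalk, protein, other.
reference: "7K00 (fill in residue ranges)"
blocks:
  - name: core
    category: core
    selectors: [{chain: A, start: 1, end: 1}]
  - name: CP
    category: CP
    selectors: [{chain: A, start: 1, end: 1}]
  - name: L1_stalk
    category: L1_stalk
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H38
    category: other
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H68
    category: H68_69
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H69
    category: H68_69
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H71
    category: PTC
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H73
    category: PTC
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H89
    category: PTC
    selectors: [{chain: A, start: 1, end: 1}]
  - name: H90_93
    category: PTC
    selectors: [{chain: A, start: 1, end: 1}]
  - name: uL16
    category: protein
    selectors: [{chain: L, start: 1, end: 1}]
  - name: bL33
    category: protein
    selectors: [{chain: Z, start: 1, end: 1}]
  - name: bL35
    category: protein
    selectors: [{chain: Y, start: 1, end: 1}]
  - name: bL36
    category: protein
    selectors: [{chain: X, start: 1, end: 1}]
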