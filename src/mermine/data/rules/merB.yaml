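# Essential catalytic residues of organomercurial lyase (MerB), in the
# numbering of the E. coli reference (position 1 = first residue of the
# deposited sequence).
family: merB
reference_id: P77072
rules:
  - ref_pos: 93
    allowed: [Y]
    taxon: any
    label: catalytic tyrosine
  - ref_pos: 159
    allowed: [C]
    taxon: any
    label: catalytic cysteine
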