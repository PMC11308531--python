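# Essential catalytic residues of mercuric reductase (MerA), in the
# numbering of the Bacillus sp. RC607 reference (position 1 = first
# residue of the deposited sequence).
family: merA
reference_id: BAB62433
rules:
  - ref_pos: 207
    allowed: [C]
    taxon: any
    label: active-site cysteine
  - ref_pos: 212
    allowed: [C]
    taxon: any
    label: active-site cysteine
  - ref_pos: 264
    allowed: [Y]
    taxon: any
    label: tyrosine
  - ref_pos: 605
    allowed: [Y]
    taxon: bacteria
    label: tyrosine (bacterial lineages)
  - ref_pos: 605
    allowed: [F]
    taxon: archaea
    label: phenylalanine (archaeal lineages)
  - ref_pos: 628
    allowed: [C]
    taxon: any
    label: C-terminal vicinal cysteine
  - ref_pos: 629
    allowed: [C]
    taxon: any
    label: C-terminal vicinal cysteine
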