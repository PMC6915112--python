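{
  "description": "Published genome-wide SNP tallies for the 62-gametophyte resequencing study; inputs for share arithmetic.",
  "n_total_snps": 46499,
  "n_identical_het_total": 22640,
  "n_nonrepeat_snps": 9989,
  "n_both_parents_het_identical": 6755,
  "n_one_parent_het": 1704,
  "n_parents_hom_different": 25
}
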