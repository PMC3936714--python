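# Mimic of the Halorubrum lacusprofundi oriC2 homolog: same origin
# architecture but only three ORB elements in its downstream titration
# region (the region length is a package choice; the source describes only
# the element count).
name: hla_oriC2_mimic
seed: 303
replicon_length: 60000
gc_background: 0.6
origin_position: 20000
origin:
  name: oriC2hla
  at_core_len: 150
  at_core_fraction: 0.85
  gstring_len: 8
  enhancer_arm: null
  titration_orb_count: 3
  titration_region_len: 300
  cdc6_gene_len: 1200
  cdc6_offset: 100
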