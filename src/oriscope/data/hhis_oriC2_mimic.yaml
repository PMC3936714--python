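# Mimic of the second chromosomal origin oriC2: no enhancer repeat, but an
# ORB-rich titration cluster (11 elements in a 722-bp intergenic region)
# directly downstream of the cdc6 gene.
name: hhis_oriC2_mimic
seed: 202
replicon_length: 60000
gc_background: 0.6
origin_position: 20000
origin:
  name: oriC2
  at_core_len: 150
  at_core_fraction: 0.85
  gstring_len: 8
  enhancer_arm: null
  titration_orb_count: 11
  titration_region_len: 722
  cdc6_gene_len: 1200
  cdc6_offset: 100
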