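# Mimic of the minimal chromosomal origin oriC1m: inverted ORB pair with
# G-string extensions, AT-rich core, G-rich inverted-repeat enhancer arms,
# adjacent cdc6 gene; no downstream titration cluster.
name: hhis_oriC1_mimic
seed: 101
replicon_length: 60000
gc_background: 0.6
origin_position: 20000
origin:
  name: oriC1
  at_core_len: 150
  at_core_fraction: 0.85
  gstring_len: 8
  enhancer_arm: GGGGAGGGGG
  titration_orb_count: 0
  titration_region_len: 0
  cdc6_gene_len: 1200
  cdc6_offset: 100
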