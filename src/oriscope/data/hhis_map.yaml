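# Replication map of Haloarcula hispanica: three replicons, seven
# origin/cdc6 pairings (two of them dormant on the minichromosome), four
# cdc6 genes without an associated origin, one titration region (oriC2D)
# regulating oriC2, and cdc6A essential beyond replication initiation.
origins:
  - {name: oriC1, replicon: chromosome, cognate: cdc6A}
  - {name: oriC2, replicon: chromosome, cognate: cdc6E, titration_region: oriC2D}
  - {name: oriC4, replicon: minichromosome, cognate: cdc6G, active: false}
  - {name: oriC5, replicon: minichromosome, cognate: cdc6H, active: false}
  - {name: oriC6, replicon: minichromosome, cognate: cdc6I}
  - {name: oriC7, replicon: minichromosome, cognate: cdc6J}
  - {name: oriP, replicon: pHH400, cognate: cdc6K}
free_initiators: [cdc6B, cdc6C, cdc6D, cdc6F]
essential_other: [cdc6A]
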