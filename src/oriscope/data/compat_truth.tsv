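label	carried	host_deleted	expected
pOC1-A in wild type	oriC1		episomal
pOC2-A in wild type	oriC2		integrative
pOC2-A in del-oriC2	oriC2	oriC2	episomal
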