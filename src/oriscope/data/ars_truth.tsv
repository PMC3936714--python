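label	carried	host_deleted	expected
pOC2-A in del-oriC2-cdc6E	oriC2	oriC2,cdc6E	ars_negative
pOC2-B in del-oriC2-cdc6E	oriC2,cdc6E	oriC2,cdc6E	ars_positive
pOC6-A in del-oriC6-cdc6I	oriC6	oriC6,cdc6I	ars_negative
pOC6-B in del-oriC6-cdc6I	oriC6,cdc6I	oriC6,cdc6I	ars_positive
pOC7-A in del-oriC7-cdc6J	oriC7	oriC7,cdc6J	ars_negative
pOC7-B in del-oriC7-cdc6J	oriC7,cdc6J	oriC7,cdc6J	ars_positive
pOC2-A in del-oriC2	oriC2	oriC2	ars_positive
pOC6-A in del-oriC6	oriC6	oriC6	ars_positive
pOC7-A in del-oriC7	oriC7	oriC7	ars_positive
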