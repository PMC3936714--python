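source	label	deleted	expected
ori_multi	DF60 del-oriC1	oriC1	obtained
ori_multi	DF60 del-oriC2	oriC2	obtained
ori_multi	DF60 del-oriC1 del-oriC2	oriC1,oriC2	not_obtained
ori_multi	DF60 del-oriC2 del-oriC1	oriC2,oriC1	not_obtained
ori_multi	DF60 del-oriC4 del-oriC5	oriC4,oriC5	obtained
ori_multi	DF60 del-oriC4 del-oriC5 del-oriC6	oriC4,oriC5,oriC6	obtained
ori_multi	DF60 del-oriC4 del-oriC5 del-oriC7	oriC4,oriC5,oriC7	obtained
ori_multi	DF60 del-oriC6 del-oriC7	oriC6,oriC7	not_obtained
ori_multi	DF60 del-oriC7 del-oriC6	oriC7,oriC6	not_obtained
cdc6_multi	DF60 del-cdc6D del-cdc6E	cdc6D,cdc6E	obtained
cdc6_multi	DF60 del-cdc6D del-cdc6E del-cdc6C	cdc6D,cdc6E,cdc6C	obtained
cdc6_multi	DF60 del-cdc6D del-cdc6E del-cdc6C del-cdc6B	cdc6D,cdc6E,cdc6C,cdc6B	obtained
cdc6_multi	DF60 del-cdc6D del-cdc6E del-cdc6C del-cdc6B del-cdc6F	cdc6D,cdc6E,cdc6C,cdc6B,cdc6F	obtained
cdc6_multi	DF60 del-cdc6G del-cdc6H	cdc6G,cdc6H	obtained
cdc6_multi	DF60 del-cdc6G del-cdc6H del-cdc6I	cdc6G,cdc6H,cdc6I	obtained
cdc6_multi	DF60 del-cdc6G del-cdc6H del-cdc6J	cdc6G,cdc6H,cdc6J	obtained
cdc6_multi	DF60 del-cdc6I del-cdc6J	cdc6I,cdc6J	not_obtained
cdc6_multi	DF60 del-cdc6J del-cdc6I	cdc6J,cdc6I	not_obtained
cdc6_multi	DF60 del-cdc6DECBF del-cdc6G	cdc6D,cdc6E,cdc6C,cdc6B,cdc6F,cdc6G	obtained
cdc6_multi	DF60 del-cdc6DECBF del-cdc6G del-cdc6H	cdc6D,cdc6E,cdc6C,cdc6B,cdc6F,cdc6G,cdc6H	obtained
cdc6_multi	DF60 del-cdc6DECBFGH del-cdc6J	cdc6D,cdc6E,cdc6C,cdc6B,cdc6F,cdc6G,cdc6H,cdc6J	obtained
cdc6_multi	DF60 del-cdc6DECBFGH del-cdc6I	cdc6D,cdc6E,cdc6C,cdc6B,cdc6F,cdc6G,cdc6H,cdc6I	obtained
single	del-oriC1	oriC1	obtained
single	del-oriC2	oriC2	obtained
single	del-oriC4	oriC4	obtained
single	del-oriC5	oriC5	obtained
single	del-oriC6	oriC6	obtained
single	del-oriC7	oriC7	obtained
single	del-oriP	oriP	not_obtained
single	del-cdc6A	cdc6A	obtained_sick
single	del-cdc6E	cdc6E	obtained
single	del-cdc6G	cdc6G	obtained
single	del-cdc6H	cdc6H	obtained
single	del-cdc6I	cdc6I	obtained
single	del-cdc6J	cdc6J	obtained
single	del-cdc6K	cdc6K	not_obtained
oriC2_region	del-oriC2D	oriC2D	not_obtained
oriC2_region	del-oriC2L	oriC2,cdc6E,oriC2D	obtained
oriC2_region	del-oriC2 del-oriC2D	oriC2,oriC2D	obtained
oriC2_region	del-oriC1 del-oriC2D	oriC1,oriC2D	not_obtained
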