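class	I	II	III	IV	V	VI	VII	VIII	IX	X	XI	XII
enolase	0	0	0	0	0	0	0	0	0	0	513	1979
D-galactonate dehydratase	0	0	0	0	0	0	0	0	0	456	17	1
rhamnonate dehydratase	0	87	0	0	123	0	0	0	0	0	12	2
L-fuconate dehydratase	0	0	0	0	0	0	165	0	0	0	18	0
D-tartrate dehydratase	0	0	92	0	0	0	0	0	0	0	6	0
L-talarate/galactarate dehydratase	0	0	0	94	0	0	0	0	0	0	4	0
dipeptide epimerase	0	0	0	0	0	0	0	0	363	0	82	3
o-succinylbenzoate synthase	0	0	0	0	0	140	0	0	19	0	204	7
N-succinylamino acid racemase 2	0	0	0	0	0	0	0	0	61	0	9	0
glucarate dehydratase	0	0	0	0	0	0	0	177	0	0	16	0
mannonate dehydratase	80	0	0	0	0	0	0	0	0	0	4	0
methylaspartate ammonia-lyase	0	0	0	0	0	0	0	0	0	0	57	0
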