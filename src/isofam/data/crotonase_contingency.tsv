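class	I	II	III	IV	V	VI	VII	VIII	IX	X	XI	XII
enoyl-CoA hydratase	0	0	0	0	0	34	0	0	0	227	404	842
methylglutaconyl-CoA hydratase	0	0	0	0	0	0	0	0	252	3	0	14
1,4-dihydroxy-2-napthoyl-CoA synthase	0	0	0	0	0	0	0	217	0	0	0	0
delta(3,5)-delta(2,4)-dienoyl-CoA isomerase	0	0	0	0	0	0	201	0	0	0	0	0
1,2-epoxyphenylacetyl-CoA isomerase	0	0	0	0	0	143	0	0	0	0	0	0
dodecenoyl-CoA delta-isomerase (mitochondrial)	0	0	0	0	84	0	0	0	0	1	0	2
dodecenoyl-CoA delta-isomerase (peroxisomal)	0	0	58	0	0	1	0	0	0	3	0	3
diffusible signal factor (DSF) synthase	0	55	0	0	0	0	0	0	0	0	0	0
crotonobetainyl-CoA hydratase	0	0	0	0	0	0	0	0	0	47	0	0
polyketide biosynthesis enoyl-CoA hydratase	0	0	0	35	0	0	0	0	1	4	0	0
feruloyl-CoA hydratase/lyase	0	0	0	33	0	0	0	0	0	0	0	0
methylmalonyl-CoA decarboxylase	29	0	0	0	0	0	0	0	0	1	0	0
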