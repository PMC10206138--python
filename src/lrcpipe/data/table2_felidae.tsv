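category	Acinonyx_jubatus	Felis_catus	Felis_chaus	Leopardus_geoffroyi	Lynx_canadensis	Neofelis_nebulosa	Panthera_leo	Panthera_tigris	Prionailurus_bengalensis	Prionailurus_viverrinus
LILRA_4Ig	0/2	2/0	2/0	2/0	1/1	2/0	2/0	1/1	2/0	2/0
LILRB_4Ig	3/0	3/0	3/0	3/0	3/0	3/0	3/0	2/1	3/0	3/0
LILRA_2Ig	1/0	1/0	1/0	1/0	1/0	1/0	1/0	1/0	1/0	1/0
LILRB_2Ig	0/1	1/0	1/0	1/0	1/0	0/1	1/0	1/0	1/0	1/0
total	4/3	7/0	7/0	7/0	6/1	6/1	7/0	5/2	7/0	7/0
novel_ig_like	1/0/1	1/0/1	1/0/1	1/0/1	0/0/0	1/0/1	1/0/1	1/0/1	1/0/1	1/0/1
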