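category	Mustela_erminea	Meles_meles	Neogale_vison	Lutra_lutra
LILRA_4Ig	4/4	2/6	3/10	6/1
LILRB_4Ig	3/2	2/2	3/3	3/0
LILRA_3Ig	0/0	0/1	0/0	0/0
LILRB_3Ig	0/0	0/1	0/0	0/0
LILRA_2Ig	0/0	0/0	0/2	0/0
LILRB_2Ig	1/0	0/1	0/2	0/1
neither_pseudogenes	1	0	0	1
total	8/7	4/11	6/17	9/3
fragments	1	2	3	2
lone_ig	4	5	4	2
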