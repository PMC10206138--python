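category	Vulpes_lagopus	Vulpes_ferrilata	Canis_lupus_familiaris	Canis_lupus_dingo	Canis_lupus|with_dup	Canis_lupus|without_dup
LILRA_4Ig	1/2	1/2	1/2	1/1	1/3	1/2
LILRB_4Ig	3/1	3/1	3/0	3/0	4/2	3/1
LILRA_2Ig	1/0	1/0	0/1	0/1	0/1	0/1
total	5/3	5/3	4/3	4/2	5/6	4/4
novel_ig_like	0/0/1	0/0/1	0/0/1	0/1/0	0/1/0	0/1/0
fragments	1	1	1	2	7	5
lone_ig	4	4	1	3	2	1
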