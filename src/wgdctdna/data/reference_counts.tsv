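# Stratum-level counts from a published colorectal cancer ctDNA cohort (n=701).
# ctdna_pos / ctdna_neg: patients with and without preoperative ctDNA detection.
# is_reference marks the reference level of each characteristic.
stratum	characteristic	level	is_reference	ctdna_pos	ctdna_neg
overall	uicc_stage	I	1	53	88
overall	uicc_stage	II	0	226	110
overall	uicc_stage	III	0	165	59
overall	location	right colon	1	185	133
overall	location	left colon	0	152	71
overall	location	rectum	0	107	53
overall	histology	adenocarcinoma	1	414	236
overall	histology	other	0	30	21
overall	venous_invasion	not detected	1	291	195
overall	venous_invasion	detected	0	145	59
overall	mmr	proficient	1	355	210
overall	mmr	deficient	0	81	40
overall	wgd	no	1	188	136
overall	wgd	yes	0	256	121
I	location	right colon	1	17	37
I	location	left colon	0	13	24
I	location	rectum	0	23	27
I	histology	adenocarcinoma	1	51	83
I	histology	other	0	2	5
I	venous_invasion	not detected	1	45	78
I	venous_invasion	detected	0	8	8
I	mmr	proficient	1	41	73
I	mmr	deficient	0	12	13
I	wgd	no	1	18	49
I	wgd	yes	0	35	39
II	location	right colon	1	105	68
II	location	left colon	0	79	29
II	location	rectum	0	42	13
II	histology	adenocarcinoma	1	208	96
II	histology	other	0	18	14
II	venous_invasion	not detected	1	169	86
II	venous_invasion	detected	0	50	23
II	mmr	proficient	1	169	84
II	mmr	deficient	0	52	23
II	wgd	no	1	104	66
II	wgd	yes	0	122	44
III	location	right colon	1	63	28
III	location	left colon	0	60	18
III	location	rectum	0	42	13
III	histology	adenocarcinoma	1	155	57
III	histology	other	0	10	2
III	venous_invasion	not detected	1	77	31
III	venous_invasion	detected	0	87	28
III	mmr	proficient	1	145	53
III	mmr	deficient	0	17	4
III	wgd	no	1	66	21
III	wgd	yes	0	99	38
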