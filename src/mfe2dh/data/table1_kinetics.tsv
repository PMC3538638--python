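protein	v_max	v_max_se	k_m	k_m_se	k_cat	k_cat_over_k_m	t_m
NATIVE	4.44	0.21	0.54	0.11	1330	2460	58
T15A							49
N158D	0.16	0.01	8.63	1.14	48.6	5.63	59
E232K	2.59	0.21	0.38	0.11	777	2050	50
R248C	1.10	0.02	0.60	0.07	331	555	56
W249G	0.019	0.001	2.68	0.47	5.7	2.1	58
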