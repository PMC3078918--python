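construct_id	km_atp_uM	km_atp_se_uM	vmax_app_per_pmol	vmax_app_se	pmol_per_reaction
JAK2_JH1	44	6	3467	180.7	0.04
JAK2_JH1JH2_WT	88	9	150	9	2.0
JAK2_JH1JH2_V617F	106	11	493	19	0.4
JAK3_JH1	35	5			1.2
JAK2_K882D			0	0	2.0
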