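peptide_id	construct	vmax_km	vmax_km_se	r_squared	fold_change	pct_total
EGFR_1103_1115	JAK2_JH1JH2_WT	0.016	0.008	0,378	1	1
EGFR_1165_1177	JAK2_JH1JH2_WT	0.062	0.006	0,889	1	2
EGFR_1190_1202	JAK2_JH1JH2_WT	0.314	0.020	0,941	1	11
EPOR_361_373	JAK2_JH1JH2_WT	0.079	0.009	0,822	1	3
EPOR_419_431	JAK2_JH1JH2_WT	0.129	0.006	0,967	1	5
ERBB2_1241_1253	JAK2_JH1JH2_WT	0.241	0.017	0,923	1	9
FAK1_569_581	JAK2_JH1JH2_WT	0.044	0.004	0,897	1	2
FAK2_572_584	JAK2_JH1JH2_WT	0.143	0.010	0,927	1	5
INSR_992_1004	JAK2_JH1JH2_WT	0.055	0.005	0,893	1	2
JAK1_1015_1027	JAK2_JH1JH2_WT	0.143	0.008	0,957	1	5
JAK2_563_577	JAK2_JH1JH2_WT	0.053	0.005	0,894	1	2
PGFRB_1002_1014	JAK2_JH1JH2_WT	0.032	0.004	0,826	1	1
PGFRB_1014_1028	JAK2_JH1JH2_WT	0.231	0.015	0,937	1	8
PGFRB_572_584	JAK2_JH1JH2_WT	0.375	0.016	0,972	1	13
PGFRB_709_721	JAK2_JH1JH2_WT	0.022	0.002	0,887	1	1
PGFRB_768_780	JAK2_JH1JH2_WT	0.027	0.003	0,867	1	1
PGFRB_771_783	JAK2_JH1JH2_WT	0.043	0.004	0,894	1	2
PP2AB_297_309	JAK2_JH1JH2_WT	0.091	0.004	0,973	1	3
RON_1346_1358	JAK2_JH1JH2_WT	0.197	0.019	0,901	1	7
RON_1353_1365	JAK2_JH1JH2_WT	0.148	0.009	0,947	1	5
STA5A_687_699	JAK2_JH1JH2_WT	0.106	0.007	0,946	1	4
STAT1_694_706	JAK2_JH1JH2_WT	0.033	0.004	0,843	1	1
STAT3_698_710	JAK2_JH1JH2_WT	0.066	0.005	0,927	1	2
STAT4_686_698	JAK2_JH1JH2_WT	0.027	0.003	0,846	1	1
EGFR_1103_1115	JAK2_JH1JH2_V617F	0.061	0.017	0,711	4	1
EGFR_1165_1177	JAK2_JH1JH2_V617F	0.159	0.006	0,981	3	2
EGFR_1190_1202	JAK2_JH1JH2_V617F	0.956	0.041	0,971	3	10
EPOR_361_373	JAK2_JH1JH2_V617F	0.320	0.019	0,946	4	3
EPOR_419_431	JAK2_JH1JH2_V617F	0.366	0.021	0,948	3	4
ERBB2_1241_1253	JAK2_JH1JH2_V617F	0.703	0.053	0,918	3	8
FAK1_569_581	JAK2_JH1JH2_V617F	0.163	0.006	0,980	4	2
FAK2_572_584	JAK2_JH1JH2_V617F	0.441	0.012	0,987	3	5
INSR_992_1004	JAK2_JH1JH2_V617F	0.136	0.011	0,903	2	1
JAK1_1015_1027	JAK2_JH1JH2_V617F	0.446	0.026	0,946	3	5
JAK2_563_577	JAK2_JH1JH2_V617F	0.126	0.008	0,935	2	1
PGFRB_1002_1014	JAK2_JH1JH2_V617F	0.130	0.006	0,971	4	1
PGFRB_1014_1028	JAK2_JH1JH2_V617F	0.784	0.025	0,984	3	8
PGFRB_572_584	JAK2_JH1JH2_V617F	1.090	0.060	0,953	3	12
PGFRB_709_721	JAK2_JH1JH2_V617F	0.078	0.005	0,942	4	1
PGFRB_768_780	JAK2_JH1JH2_V617F	0.083	0.006	0,917	3	1
PGFRB_771_783	JAK2_JH1JH2_V617F	0.135	0.005	0,980	3	1
PP2AB_297_309	JAK2_JH1JH2_V617F	0.335	0.014	0,972	4	4
RON_1346_1358	JAK2_JH1JH2_V617F	0.675	0.035	0,959	3	7
RON_1353_1365	JAK2_JH1JH2_V617F	0.762	0.021	0,988	5	8
STA5A_687_699	JAK2_JH1JH2_V617F	0.425	0.017	0,974	4	5
STAT1_694_706	JAK2_JH1JH2_V617F	0.149	0.007	0,965	4	2
STAT3_698_710	JAK2_JH1JH2_V617F	0.255	0.008	0,984	4	3
STAT4_686_698	JAK2_JH1JH2_V617F	0.116	0.009	0,911	4	1
EGFR_1103_1115	JAK2_JH1	0.345	0.140	0,670	22	1
EGFR_1165_1177	JAK2_JH1	0.880	0.075	0,895	14	2
EGFR_1190_1202	JAK2_JH1	2.928	0.311	0,872	9	6
EPOR_361_373	JAK2_JH1	2.560	0.268	0,851	32	5
EPOR_419_431	JAK2_JH1	2.471	0.241	0,868	19	5
ERBB2_1241_1253	JAK2_JH1	2.905	0.350	0,852	12	6
FAK1_569_581	JAK2_JH1	0.735	0.064	0,890	17	1
FAK2_572_584	JAK2_JH1	3.456	0.128	0,984	24	7
INSR_992_1004	JAK2_JH1	1.252	0.088	0,939	23	2
JAK1_1015_1027	JAK2_JH1	3.623	0.248	0,947	25	7
JAK2_563_577	JAK2_JH1	0.889	0.052	0,949	17	2
PGFRB_1002_1014	JAK2_JH1	0.879	0.051	0,948	27	2
PGFRB_1014_1028	JAK2_JH1	3.946	0.561	0,818	17	8
PGFRB_572_584	JAK2_JH1	3.750	0.369	0,888	10	7
PGFRB_709_721	JAK2_JH1	0.433	0.045	0,850	20	1
PGFRB_768_780	JAK2_JH1	0.500	0.037	0,920	18	1
PGFRB_771_783	JAK2_JH1	0.908	0.070	0,913	21	2
PP2AB_297_309	JAK2_JH1	1.626	0.079	0,964	18	3
RON_1346_1358	JAK2_JH1	7.388	0.803	0,914	38	15
RON_1353_1365	JAK2_JH1	3.241	0.260	0,906	22	6
STA5A_687_699	JAK2_JH1	2.087	0.129	0,942	20	4
STAT1_694_706	JAK2_JH1	0.860	0.054	0,940	26	2
STAT3_698_710	JAK2_JH1	0.819	0.069	0,933	12	2
STAT4_686_698	JAK2_JH1	0.505	0.035	0,928	19	1
EGFR_1103_1115	JAK3_JH1	0.073	0.003	0,968	5	1
EGFR_1165_1177	JAK3_JH1	0.474	0.025	0,959	8	6
EGFR_1190_1202	JAK3_JH1	0.330	0.024	0,921	1	4
EPOR_361_373	JAK3_JH1	0.122	0.007	0,946	2	2
EPOR_419_431	JAK3_JH1	0.210	0.009	0,972	2	3
ERBB2_1241_1253	JAK3_JH1	0.304	0.025	0,899	1	4
FAK1_569_581	JAK3_JH1	0.199	0.014	0,921	4	3
FAK2_572_584	JAK3_JH1	0.631	0.033	0,959	4	8
INSR_992_1004	JAK3_JH1	0.330	0.010	0,985	6	4
JAK1_1015_1027	JAK3_JH1	0.643	0.034	0,957	4	8
JAK2_563_577	JAK3_JH1	0.107	0.005	0,960	2	1
PGFRB_1002_1014	JAK3_JH1	0.069	0.005	0,909	2	1
PGFRB_1014_1028	JAK3_JH1	0.433	0.022	0,962	2	6
PGFRB_572_584	JAK3_JH1	0.818	0.082	0,861	2	11
PGFRB_709_721	JAK3_JH1	0.065	0.006	0,883	3	1
PGFRB_768_780	JAK3_JH1	0.191	0.011	0,950	7	3
PGFRB_771_783	JAK3_JH1	0.220	0.006	0,989	5	3
PP2AB_297_309	JAK3_JH1	0.779	0.039	0,962	9	10
RON_1346_1358	JAK3_JH1	0.408	0.021	0,961	2	5
RON_1353_1365	JAK3_JH1	0.313	0.012	0,978	2	4
STA5A_687_699	JAK3_JH1	0.073	0.004	0,957	1	1
STAT1_694_706	JAK3_JH1	0.034	0.004	0,847	1	0
STAT3_698_710	JAK3_JH1	0.071	0.003	0,979	1	1
STAT4_686_698	JAK3_JH1	0.091	0.007	0,904	3	1
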