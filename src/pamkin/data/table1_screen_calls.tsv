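peptide_id	sequence	protein	JAK2_JH1JH2_WT	JAK2_JH1JH2_V617F	JAK2_JH1
41_654_666	LDGENIYIRHSNL	Protein 4.1			X
ACHD_383_395	YISKAEEYFLLKS	Acetylcholine receptor subunit delta precursor	X	X	X
B3AT_39_51	TEATATDYHTTSH	Band 3 anion transport protein		X	X
C1R_199_211	TEASGYISSLEYP	Complement C1r subcomponent precursor		X	X
CALM_93_105	FDKDGNGYISAAE	Calmodulin		X	X
CALM_95_107	KDGNGYISAAELR	Calmodulin		X	X
CBL_693_705	EGEEDTEYMTPSS	E3 ubiquitin-protein ligase CBL			X
CRK_214_226	GPPEPGPYAQPSV	Proto-oncogene C-crk		X	X
CTNB1_79_91	VADIDGQYAMTRA	Catenin beta-1			X
DYR1A_212_224	KHDTEMKYYIVHL	Dual specificity tyrosine-phosphorylation-regulated kinase 1A			X
EFS_246_258	GGTDEGIYDVPLL	Embryonal Fyn-associated substrate			X
EGFR_1103_1115	GSVQNPVYHNQPL	Epidermal growth factor receptor precursor			X
EGFR_1165_1177	ISLDNPDYQQDFF	Epidermal growth factor receptor precursor		X	X
EGFR_1190_1202	STAENAEYLRVAP	Epidermal growth factor receptor precursor	X	X	X
EPHA2_765_777	EDDPEATYTTSGG	Ephrin type-A receptor 2 precursor			X
EPHA4_589_601	LNQGVRTYVDPFT	Ephrin type-A receptor 4 precursor		X	X
EPHB1_771_783	DDTSDPTYTSSLG	Ephrin type-B receptor 1 precursor			X
EPOR_361_373	SEHAQDTYLVLDK	Erythropoietin receptor precursor	X	X	X
EPOR_419_431	ASAASFEYTILDP	Erythropoietin receptor precursor	X	X	X
ERBB2_1241_1253	PTAENPEYLGLDV	Receptor Tyrosine-protein kinase erbB-2 precursor	X	X	X
ERBB4_1181_1193	QALDNPEYHNASN	Receptor tyrosine-protein kinase erbB-4 precursor	X	X	X
ERBB4_1277_1289	IVAENPEYLSEFS	Receptor tyrosine-protein kinase erbB-4 precursor	X	X	X
FABPH_13_25	DSKNFDDYMKSLG	Fatty acid-binding protein, heart			X
FAK1_569_581	RYMEDSTYYKASK	Focal adhesion kinase 1		X	X
FAK2_572_584	RYIEDEDYYKASV	Protein tyrosine kinase 2 beta		X	X
FER_707_719	RQEDGGVYSSSGL	Proto-oncogene tyrosine-protein kinase FER			X
FGFR1_761_773	TSNQEYLDLSMPL	Fibroblast growth factor receptor 1 precursor	X	X	X
FGFR2_762_774	TLTTNEEYLDLSQ	Fibroblast growth factor receptor 2 precursor	X	X	X
FGFR3_641_653	DVHNLDYYKKTTN	Fibroblast growth factor receptor 3 precursor		X	X
FGFR3_753_765	TVTSTDEYLDLSA	Fibroblast growth factor receptor 3 precursor	X	X	X
INSR_992_1004	YASSNPEYLSASD	Insulin receptor precursor	X	X	X
JAK1_1015_1027	AIETDKEYYTVKD	Tyrosine-protein kinase JAK1	X	X	X
JAK2_563_577	VRREVGDYGQLHETE	Tyrosine-protein kinase JAK2		X	X
KSYK_518_530	ALRADENYYKAQT	Tyrosine-protein kinase SYK	X	X	X
LAT_194_206	MESIDDYVNVPES	Linker for activation of T-cells family member 1	X	X	X
MK07_211_223	AEHQYFMTEYVAT	Mitogen-activated protein kinase 7	X	X	X
MK12_178_190	ADSEMTGYVVTRW	Mitogen-activated protein kinase 12	X	X	X
MK14_173_185	RHTDDEMTGYVAT	Mitogen-activated protein kinase 14	X	X	X
NTRK2_509_521	PVIENPQYFGITN	BDNF/NT-3 growth factors receptor precursor			X
NTRK2_696_708	GMSRDVYSTDYYR	BDNF/NT-3 growth factors receptor precursor	X	X	X
PAXI_111_123	VGEEEHVYSFPNK	Paxillin			X
PAXI_24_36	FLSEETPYSYPTG	Paxillin			X
PGFRB_1002_1014	LDTSSVLYTAVQP	Beta-type platelet-derived growth factor receptor precursor			X
PGFRB_1014_1028	PNEGDNDYIIPLPDP	Beta-type platelet-derived growth factor receptor precursor	X	X	X
PGFRB_572_584	VSSDGHEYIYVDP	Beta-type platelet-derived growth factor receptor precursor		X	X
PGFRB_709_721	RPPSAELYSNALP	Beta-type platelet-derived growth factor receptor precursor			X
PGFRB_768_780	SSNYMAPYDNYVP	Beta-type platelet-derived growth factor receptor precursor			X
PGFRB_771_783	YMAPYDNYVPSAP	Beta-type platelet-derived growth factor receptor precursor			X
PP2AB_297_309	EPHVTRRTPDYFL	Serine/threonine-protein phosphatase 2A catalytic beta	X	X	X
PRRX2_202_214	WTASSPYSTVPPY	Paired mesoderm homeobox protein 2			X
RON_1346_1358	SALLGDHYVQLPA	Macrophage-stimulating protein receptor precursor	X	X	X
RON_1353_1365	YVQLPATYMNLGP	Macrophage-stimulating protein receptor precursor	X	X	X
STA5A_687_699	LAKAVDGYVKPQI	Signal transducer and activator of transcription 5A	X	X	X
STAT1_694_706	DGPKGTGYIKTEL	Signal transducer and activator of transcription 1-alpha/beta			X
STAT3_698_710	DPGSAAPYLKTKF	Signal transducer and activator of transcription 3		X	X
STAT4_686_698	TERGDKGYVPSVF	Signal transducer and activator of transcription 4			X
VGFR1_1162_1174	VQQDGKDYIPINA	Vascular endothelial growth factor receptor 1 precursor		X	X
VGFR1_1320_1332	SSSPPPDYNSVVL	Vascular endothelial growth factor receptor 1 precursor	X	X	X
VGFR1_1326_1338	DYNSVVLYSTPPI	Vascular endothelial growth factor receptor 1 precursor	X	X	X
VGFR2_1052_1064	DIYKDPDYVRKGD	Vascular endothelial growth factor receptor 2			X
VGFR2_1168_1180	AQQDGKDYIVLPI	Vascular endothelial growth factor receptor 2	X	X	X
VINC_815_827	KSFLDSGYRILGA	Vinculin	X	X	X
ZAP70_485_497	ALGADDSYYTARS	Tyrosine-protein kinase ZAP-70	X	X	X
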