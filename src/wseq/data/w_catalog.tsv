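gene	description	location	fpkm_blastoderm_female	fpkm_gonad_female	dna_identity_pct	protein_identity_pct	dnds	is_small_rna	is_novel	lacks_z_gametologue
ATP5A1-W	ATP synthase subunit alpha	ChrW W_random	101	155	89.3	95.4	0.280	0	0	0
BTF3-W	Transcription factor BTF3-like	Autosome	86.3	141	90.9	94.4	0.160	0	0	0
C18ORF25-W	Uncharacterized protein C18ORF25	ChrW W_random ChrUn	0.874	3.93	90.3	83.7	0.434	0	0	0
CHD1-W	Chromodomain helicase DNA binding protein	ChrW W_random autosomal	6.81	9.35	86.8	88.1	0.126	0	0	0
FAF	Female Associated Factor	ChrW W_random	15	21.2				0	0	1
GOLPH3-W	Golgi phosphoprotein 3-like	ChrUn	2.82	24.9	92.7	95.6	0.080	0	0	0
HINT-W	Histidine triad nucleotide binding protein	ChrW W_random	1780	1170	41.0	48.5	0.608	0	0	0
HNRPK-W	Heterogeneous nuclear ribonucleoprotein K	ChrUn	103	100	94.2	99.3	0.040	0	0	0
KCMF1-W	E3 ubiquitin-protein ligase KCMF1-like	ChrW W_random	10.1	21.6	92.0	93.2	0.181	0	0	0
MIER3-W	Mesoderm induction early response 3	ChrUn	7.42	19.9	92.9	92.5	0.265	0	0	0
NEDD4-like-W	Neural precursor cell expressed developmentally downregulated 4-like	ChrUn	0.048	1.92	82.4	83.0	0.209	0	0	0
NIPBL-W/SCC2-W	Nipped B/sister chromatid cohesion 2	ChrW W_random	7.78	7.39	89.9	90.0	0.148	0	0	0
RASA1-W	Ras GTPase-activating protein 1-like	ChrW W_random ChrUn	2.77	10.5	81.4	89.4	0.132	0	0	0
RPL17-W	Ribosomal protein 17	ChrUn	368	332	96.7	100.0	0.000	0	0	0
SMAD2-W	Mothers against decapentaplegic homolog 2-like	ChrW W_random	19.2	30	92.4	96.4	0.024	0	0	0
SMAD7-W	TGF-beta signal pathway antagonist Smad7	ChrUn	4.47	4.95	93.8	93.6	0.208	0	0	0
SPIN-W	Spindlin	ChrW W_random	1.8	10.6	95.7	98.5	0.045	0	0	0
ST8SIA3-W	Sia-alpha-2,3-Gal-beta-1,4-GlcNAc-R: alpha 2,8-sialyltransferase-like	ChrW W_random	4.31	3.16	94.7	95.7	0.105	0	0	0
SUB1-W	Activated RNA polymerase II transcriptional coactivator p15-like	ChrUn	11.6	26.6	94.5	96.0	0.097	0	1	0
TXN-like1-W	thioredoxin	ChrUn	7.16	19.6	94.5	95.2	0.144	0	1	0
UBAP2-W	Ubiquitin associated protein 2	ChrW W_random	16.3	11.9	92.1	89.6	0.263	0	0	0
UBE2R2-W	Ubiquitin-conjugating enzyme E2R 2	ChrW W_random	5.38	17.4	94.4	100.0	0.000	0	0	0
VCP-like-W	Valosin containing protein	ChrUn	64.4	128	95.5	99.9	0.003	0	0	0
ZFR-W	Zinc finger RNA-binding protein	Autosome ChrUn	4.47	7.51	93.8	94.1	0.172	0	0	0
ZNF532-W	Zinc finger protein 532-like	autosome	3.52	5.59	94.0	94.0	0.181	0	0	0
ZSWIM6-W	Zinc finger SWIM domain-containing protein 6-like	ChrW W_random autosome ChrUn	0.54	4.73	91.7	92.4	0.172	0	0	0
Mir-7b-W	MicroRNA 7b (in intron of HNRPK-W)	ChrUn			93.6			1	0	0
SNORD58-W 1	Small nucleolar RNA SNORD58 (in intron of RPL17-W)	ChrUn			97.0			1	0	0
SNORD58-W 2	Small nucleolar RNA SNORD58 (in intron of RPL17-W)	ChrUn			89.7			1	0	0
SNORD121A-W 1	Small nucleolar RNA SNORD121A (in intron of UBAP2-W)	ChrW W_random			90.6			1	0	0
SNORD121A-W 2	Small nucleolar RNA SNORD121A (in intron of UBAP2-W)	ChrW W_random			90.4			1	0	0
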