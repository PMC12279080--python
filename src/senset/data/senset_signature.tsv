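# Curated human-lung senescence signature (SenSet): 106 genes selected for
# differential expression between called-senescent and healthy aged cells in
# at least six lung cell types, with per-gene direction flags for two cell
# types of interest (alveolar type 1 fibroblasts, respiratory basal cells).
# Flag semantics fixed by cross-checking marginal counts (fib_up=19,
# fib_down=34, basal_up=39, basal_down=43) and pairwise overlaps
# (fib_up&basal_up=9, fib_down&basal_down=19) against the published
# per-cell-type tallies. Flags are 0/1; up/down pairs are mutually exclusive.
symbol	full_name	fib_up	fib_down	basal_up	basal_down
AAK1	AP2 Associated Kinase 1	0	0	1	0
AKR1B1	Aldo-Keto Reductase Family 1 Member B	0	0	0	0
ALDH1A1	Aldehyde Dehydrogenase 1 Family Member A1	1	0	0	1
AREG	Amphiregulin	0	0	0	1
ARPC1B	Actin Related Protein 2/3 Complex Subunit 1B	0	0	0	1
ASPH	Aspartate Beta-Hydroxylase	0	0	1	0
B2M	Beta-2-Microglobulin	0	0	0	1
BAG3	BAG Cochaperone 3	0	1	1	0
BEX3	Brain Expressed X-Linked 3	1	0	0	1
BHLHE40	Basic Helix-Loop-Helix Family Member E40	0	0	1	0
CALR	Calreticulin	0	1	0	1
CAV1	Caveolin 1	1	0	0	0
CAVIN1	Caveolae Associated Protein 1	0	0	1	0
CCL3	C-C Motif Chemokine Ligand 3	0	0	0	0
CCL3L1	C-C Motif Chemokine Ligand 3 Like 1	0	0	0	0
CCL4	C-C Motif Chemokine Ligand 4	0	1	0	0
CCN2	Cellular Communication Network Factor 2	1	0	1	0
CCND1	Cyclin D1	0	0	0	1
CD44	CD44 Molecule (IN Blood Group)	0	0	0	0
CD9	CD9 Molecule	1	0	0	1
CDKN1A	Cyclin Dependent Kinase Inhibitor 1A	0	1	0	1
CEBPB	CCAAT Enhancer Binding Protein Beta	0	0	1	0
CITED2	Cbp/P300 Interacting Transactivator With Glu/Asp Rich Carboxy-Terminal Domain 2	1	0	1	0
CLTB	Clathrin Light Chain B	0	1	0	1
CSNK1A1	Casein Kinase 1 Alpha 1	1	0	1	0
CTNNB1	Catenin Beta 1	1	0	1	0
CTSB	Cathepsin B	0	0	0	1
CXCL2	C-X-C Motif Chemokine Ligand 2	0	1	0	0
CXCL8	C-X-C Motif Chemokine Ligand 8	0	1	0	1
DEK	DEK Proto-Oncogene	0	0	0	1
DPY30	Dpy-30 Histone Methyltransferase Complex Regulatory Subunit	0	0	0	1
EDN1	Endothelin 1	0	0	1	0
EGR1	Early Growth Response 1	0	1	1	0
EIF2S2	Eukaryotic Translation Initiation Factor 2 Subunit Beta	0	1	0	1
ETS2	ETS Proto-Oncogene 2, Transcription Factor	0	0	1	0
EWSR1	EWS RNA Binding Protein 1	0	0	0	0
FOS	Fos Proto-Oncogene, AP-1 Transcription Factor Subunit	0	0	1	0
GAPDH	Glyceraldehyde-3-Phosphate Dehydrogenase	0	1	0	1
GMFG	Glia Maturation Factor Gamma	0	0	0	0
GSN	Gelsolin	1	0	0	1
GUK1	Guanylate Kinase 1	0	1	0	1
HDAC1	Histone Deacetylase 1	0	0	0	0
HMGB1	High Mobility Group Box 1	0	0	0	1
HSPA5	Heat Shock Protein Family A (Hsp70) Member 5	0	1	0	1
ID1	Inhibitor Of DNA Binding 1	0	0	0	0
ID2	Inhibitor Of DNA Binding 2	0	1	1	0
IFI16	Interferon Gamma Inducible Protein 16	0	1	0	1
IGFBP2	Insulin Like Growth Factor Binding Protein 2	0	0	1	0
IGFBP4	Insulin Like Growth Factor Binding Protein 4	0	1	0	0
IGFBP7	Insulin Like Growth Factor Binding Protein 7	1	0	0	0
IL18	Interleukin 18	0	0	1	0
IL32	Interleukin 32	0	1	0	1
IL6ST	Interleukin 6 Cytokine Family Signal Transducer	0	1	1	0
IRF3	Interferon Regulatory Factor 3	0	0	1	0
ISG15	ISG15 Ubiquitin Like Modifier	0	0	0	0
JUN	Jun Proto-Oncogene, AP-1 Transcription Factor Subunit	0	0	1	0
LGALS3	Galectin 3	0	0	0	1
LIMA1	LIM Domain And Actin Binding 1	1	0	0	0
LMNA	Lamin A/C	1	0	0	1
MAGOH	Mago Homolog, Exon Junction Complex Subunit	0	1	0	1
MAP1LC3B	Microtubule Associated Protein 1 Light Chain 3 Beta	0	1	0	0
MAP2K1	Mitogen-Activated Protein Kinase Kinase 1	0	0	1	0
MAP2K3	Mitogen-Activated Protein Kinase Kinase 3	0	0	0	0
MARCKS	Myristoylated Alanine Rich Protein Kinase C Substrate	1	0	1	0
MCL1	MCL1 Apoptosis Regulator, BCL2 Family Member	1	0	0	0
MDH1	Malate Dehydrogenase 1	0	0	0	1
MIF	Macrophage Migration Inhibitory Factor	0	1	0	1
MMP14	Matrix Metallopeptidase 14	0	1	1	0
NDRG1	N-Myc Downstream Regulated 1	0	0	1	0
NFE2L2	NFE2 Like BZIP Transcription Factor 2	0	0	0	1
NINJ1	Ninjurin 1	0	0	0	1
NME2	NME/NM23 Nucleoside Diphosphate Kinase 2	0	1	0	0
NPM1	Nucleophosmin 1	0	1	0	1
OPTN	Optineurin	0	0	1	0
PEA15	Proliferation And Apoptosis Adaptor Protein 15	0	1	0	0
PEBP1	Phosphatidylethanolamine Binding Protein 1	0	0	0	1
PKM	Pyruvate Kinase M1/2	0	1	0	1
PLAUR	Plasminogen Activator, Urokinase Receptor	0	1	1	0
PLK2	Polo Like Kinase 2	0	0	1	0
PRKCD	Protein Kinase C Delta	0	0	1	0
PSMB5	Proteasome 20S Subunit Beta 5	0	0	0	1
PSMD14	Proteasome 26S Subunit, Non-ATPase 14	0	1	0	0
PTBP1	Polypyrimidine Tract Binding Protein 1	0	0	1	0
RAB13	RAB13, Member RAS Oncogene Family	0	1	0	1
RAC1	Rac Family Small GTPase 1	0	0	1	0
RBX1	Ring-Box 1	0	0	0	1
RGL2	Ral Guanine Nucleotide Dissociation Stimulator Like 2	0	0	1	0
RHOB	Ras Homolog Family Member B	0	0	1	0
RSL1D1	Ribosomal L1 Domain Containing 1	0	1	0	1
S100A11	S100 Calcium Binding Protein A11	0	1	0	1
SELENOH	Selenoprotein H	0	0	0	1
SGK1	Serum/Glucocorticoid Regulated Kinase 1	0	0	0	1
SMARCB1	SWI/SNF Related, Matrix Associated, Actin Dependent Regulator Of Chromatin, Subfamily B, Member 1	0	0	0	0
SOD1	Superoxide Dismutase 1	0	0	0	1
SPOP	Speckle Type BTB/POZ Protein	1	0	1	0
THBS1	Thrombospondin 1	0	1	1	0
TMSB4X	Thymosin Beta 4 X-Linked	1	0	0	1
TNFAIP3	TNF Alpha Induced Protein 3	0	1	1	0
TNFRSF1A	TNF Receptor Superfamily Member 1A	1	0	1	0
TPR	Translocated Promoter Region, Nuclear Basket Protein	0	0	0	0
TXN	Thioredoxin	0	1	0	1
TXNIP	Thioredoxin Interacting Protein	0	0	1	0
VIM	Vimentin	0	0	0	0
YBX1	Y-Box Binding Protein 1	0	1	0	1
YPEL3	Yippee Like 3	1	0	1	0
ZFP36	ZFP36 Ring Finger Protein	1	0	1	0
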