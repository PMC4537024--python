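gene	description	agonist_mdm_fc	peak	refractory
ACADVL	acyl-CoA dehydrogenase, very long chain	3.3	+	+
ACSS3	acyl-CoA synthetase short-chain family member 3	2.3	-	+
AMOTL1	angiomotin like 1	1.9	-	+
ANGPTL4	angiopoietin-like 4	37.8	+	+
ANKRD1	ankyrin repeat domain 1 (cardiac muscle)	1.8	-	-
C19orf59	chromosome 19 open reading frame 59	6.7	+	+
C1orf162	chromosome 1 open reading frame 162	2.2	+	+
C1QC	complement component 1, q subcomponent, C chain	1.5	-	-
CABLES1	Cdk5 and Abl enzyme substrate 1	3.2	-	+
CACNB1	calcium channel, voltage-dependent, beta 1 subunit	2.4	+	+
CD300A	CD300a molecule	1.5	+	-
CLDND2	claudin domain containing 2	2.2	+	+
CPT1A	carnitine palmitoyltransferase 1A (liver)	3.4	+	+
CXorf21	chromosome X open reading frame 21	1.8	+	+
DLG4	discs, large homolog 4 (Drosophila)	1.6	+	+
FAM3B	family with sequence similarity 3, member B	2.7	-	+
FCGR3A	Fc fragment of IgG, low affinity IIIa, receptor (CD16a)	1.5	+	-
FCGRT	Fc fragment of IgG, receptor, transporter, alpha	1.5	+	-
FOS	FBJ murine osteosarcoma viral oncogene homolog	1.1	+	-
GPA33	glycoprotein A33 (transmembrane)	1.8	-	+
HMOX1	heme oxygenase (decycling) 1	1.3	+	-
HP	haptoglobin	2.2	-	-
HPR	haptoglobin-related protein	2.6	-	-
HS3ST1	heparan sulfate (glucosamine) 3-O-sulfotransferase 1	4.4	-	+
IL27	interleukin 27	1.2	-	-
IMPA2	inositol(myo)-1(or 4)-monophosphatase 2	2.6	+	+
INF2	inverted formin, FH2 and WH2 domain containing	1.5	-	+
KBTBD11	kelch repeat and BTB (POZ) domain containing 11	1.3	-	-
KLF11	Kruppel-like factor 11	1.4	-	-
KRT4	keratin 4	1.9	-	+
LRP5	low density lipoprotein receptor-related protein 5	6.6	+	+
MACC1	metastasis associated in colon cancer 1	1.8	+	-
MAP3K8	mitogen-activated protein kinase kinase kinase 8	1.5	-	+
MEGF9	multiple EGF-like-domains 9	1.5	+	-
MS4A14	membrane-spanning 4-domains, subfam. A, member 14	1.6	-	+
MS4A7	membrane-spanning 4-domains, subfamily A, member 7	1.6	-	-
PCOLCE2	procollagen C-endopeptidase enhancer 2	1.9	-	-
PDE1B	phosphodiesterase 1B, calmodulin-dependent	2.2	-	-
PDK4	pyruvate dehydrogenase kinase 4	99.0	+	+
PHACTR1	phosphatase and actin regulator 1	3.1	+	+
PLIN2	perilipin 2	5.5	+	+
PPP1R15B	protein phosphatase 1, regulatory subunit 15B	1.6	+	-
RBP7	retinol binding protein 7, cellular	1.8	-	+
RCN3	reticulocalbin 3, EF-hand calcium binding domain	2.6	+	+
RETN	resistin	1.3	+	+
S100Z	S100 calcium binding protein Z	3.1	+	-
SIPA1L2	signal-induced proliferation-associated 1 like 2	2.1	+	+
ST14	suppression of tumorigenicity 14 (colon carcinoma)	2.4	+	+
TCF7	transcription factor 7 (T-cell specific, HMG-box)	6.3	+	+
TMEM150B	transmembrane protein 150B	1.2	+	-
TMEM37	transmembrane protein 37	1.7	+	+
TRIM14	tripartite motif containing 14	1.6	-	+
TSKS	testis-specific serine kinase substrate	0.8	+	-
VSIG10L	V-set and immunoglobulin domain containing 10 like	1.4	+	-
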