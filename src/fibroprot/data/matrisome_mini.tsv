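gene_symbol	division	category
COL1A1	Core matrisome	Collagens
COL1A2	Core matrisome	Collagens
COL3A1	Core matrisome	Collagens
COL4A1	Core matrisome	Collagens
COL4A2	Core matrisome	Collagens
COL4A3	Core matrisome	Collagens
COL5A1	Core matrisome	Collagens
COL6A1	Core matrisome	Collagens
COL14A1	Core matrisome	Collagens
FN1	Core matrisome	ECM Glycoproteins
TNC	Core matrisome	ECM Glycoproteins
TNXB	Core matrisome	ECM Glycoproteins
POSTN	Core matrisome	ECM Glycoproteins
SPARC	Core matrisome	ECM Glycoproteins
NID1	Core matrisome	ECM Glycoproteins
FBN1	Core matrisome	ECM Glycoproteins
ELN	Core matrisome	ECM Glycoproteins
EMILIN1	Core matrisome	ECM Glycoproteins
LAMB1	Core matrisome	ECM Glycoproteins
HSPG2	Core matrisome	Proteoglycans
VCAN	Core matrisome	Proteoglycans
DCN	Core matrisome	Proteoglycans
BGN	Core matrisome	Proteoglycans
LUM	Core matrisome	Proteoglycans
SERPINH1	Matrisome-associated	ECM Regulators
SERPINE1	Matrisome-associated	ECM Regulators
LOX	Matrisome-associated	ECM Regulators
LOXL1	Matrisome-associated	ECM Regulators
MMP2	Matrisome-associated	ECM Regulators
TIMP1	Matrisome-associated	ECM Regulators
LGALS1	Matrisome-associated	ECM-affiliated Proteins
LGALS3	Matrisome-associated	ECM-affiliated Proteins
ANXA1	Matrisome-associated	ECM-affiliated Proteins
ANXA2	Matrisome-associated	ECM-affiliated Proteins
TGFB1	Matrisome-associated	Secreted Factors
S100A4	Matrisome-associated	Secreted Factors
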