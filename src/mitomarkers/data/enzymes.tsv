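name	site
AluI	AG^CT
BamHI	G^GATCC
BbsI	GAAGAC(2/6)
BsaI	GGTCTC(1/5)
BsmBI	CGTCTC(1/5)
BstXI	CCANNNNN^NTGG
DdeI	C^TNAG
EcoRI	G^AATTC
HaeIII	GG^CC
HindIII	A^AGCTT
HinfI	G^ANTC
MseI	T^TAA
NciI	CC^SGG
RsaI	GT^AC
SfcI	C^TRYAG
TaqI	T^CGA
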