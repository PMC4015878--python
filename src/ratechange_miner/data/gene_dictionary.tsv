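MTH1	MTH1
HXT3	HXT3
HXT1	HXT1
CDC13	CDC13
CDC25	CDC25
MDM2	MDM2
TP53	p53
CDKN1A	p21	waf1
CHZ1	CHZ1
HTB1	H2B	HTB1
HHT1	H3	H3K79	HHT1
SIR3	SIR3	Sir3p
SIR4	SIR4	Sir4p
CLN1	CLN1
CLN2	CLN2
NPL4	NPL4
UFD1	UFD1
CDC48	CDC48
CDC14	CDC14
CDK1	CDK1	CDC28
ISW2	ISW2
INO80	INO80
PIS1	PIS1
GPD1	GPD1	GPDI
HSP12	HSP12
HSP104	HSP104
IME1	IME1
GAL4	GAL4
SWI5	SWI5
ACE2	ACE2
FKH1	FKH1
FKH2	FKH2
NDD1	NDD1
MCM1	MCM1
SIC1	SIC1
CLB2	CLB2
HO	HO
PHO5	PHO5
GCN4	GCN4
MSN2	MSN2
MSN4	MSN4
HSF1	HSF1
RAP1	RAP1
ABF1	ABF1
REB1	REB1
TUP1	TUP1
MIG1	MIG1
SNF1	SNF1
HXK2	HXK2
CYC1	CYC1
ADH1	ADH1
PGK1	PGK1
TEF1	TEF1
RPL3	RPL3
GAL1	GAL1
GAL80	GAL80
STE12	STE12
FUS3	FUS3
KSS1	KSS1
PDR1	PDR1
YAP1	YAP1
ROX1	ROX1
HAP4	HAP4
CAT8	CAT8
ADR1	ADR1
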