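homeostasis	microglia homeostatic markers	CX3CR1	CSF1R	P2RY12	TMEM119
M1	pro-inflammatory polarization markers	IL12B	IL12A	IL23A	TNF	NOS2	CXCL10
M2	alternatively activated polarization markers	RETNLB	IL10	ARG1	MRC1
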