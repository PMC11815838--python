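variant	chain_kind	resnum	icode	wild_type	reported_pka	reported_sesa
P1	H	28		N	7.0	83.1
P2	H	33		Y	5.0	27.2
P3	H	50		R	3.6	0.0
P4	H	56		Y	6.4	51.6
P5	H	58		R	5.9	50.6
P6	H	100	A	Y	3.9	7.0
P7	L	30	A	R	6.6	57.9
P8	L	30	B	S	6.6	56.6
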