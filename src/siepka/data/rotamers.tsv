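restype	rotamer	chi1	chi2
HIS	1	62	-75
HIS	2	62	80
HIS	3	-177	-165
HIS	4	-177	-80
HIS	5	-177	60
HIS	6	-65	-70
HIS	7	-65	165
HIS	8	-65	80
ASP	1	62	-10
ASP	2	62	65
ASP	3	-177	10
ASP	4	-177	65
ASP	5	-65	-25
ASP	6	-65	30
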