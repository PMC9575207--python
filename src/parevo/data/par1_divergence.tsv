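branch	par1_total	par1_per_year	telomere_total	telomere_per_year
H	0.0105	9.652e-10	0.0082	7.543e-10
C	0.0120	1.1023e-9	0.0081	7.483e-10
HC	0.0036	1.7496e-9	0.0027	1.3179e-9
G	0.0143	1.1007e-9	0.0108	8.300e-10
HCG	0.0166	1.5248e-9	0.0120	1.1047e-9
O	0.0279	1.1696e-9	0.0210	8.819e-10
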