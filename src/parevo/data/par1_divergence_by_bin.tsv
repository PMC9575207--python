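branch	total_low	total_medium	total_high	per_year_low	per_year_medium	per_year_high
H	0.0092	0.0106	0.0119	8.411e-10	9.731e-10	1.0927e-9
C	0.0109	0.0117	0.0139	1.0042e-9	1.0764e-9	1.2797e-9
HC	0.0026	0.0039	0.0048	1.2571e-9	1.8603e-9	2.3172e-9
G	0.0134	0.0137	0.0166	1.0319e-9	1.0600e-9	1.2840e-9
HCG	0.0154	0.0177	0.0175	1.4121e-9	1.6236e-9	1.6114e-9
O	0.0243	0.0286	0.0374	1.0192e-9	1.1984e-9	1.5695e-9
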