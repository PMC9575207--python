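pop	rho	pi	theta_par	theta_a	tajimas_d	B	generation_time	ne_printed	mu_pg_printed	mu_py_printed
HUM		0.0025	0.0025	0.0009	-0.0541	0.6745
PTE	12922	0.0024	0.0026	0.0013	-0.2500	0.6801	25	14138	4.31e-8	1.72e-9
PTS	16141	0.0023	0.0026	0.0016	-0.3273	0.6064	25	17661	3.31e-8	1.32e-9
PTT	32855	0.0028	0.0039	0.0023	-1.0783	0.8125	25	35948	1.97e-8	7.9e-10
PTV	9136	0.0013	0.0014	0.0008	-0.2132	0.7302	25	9996	3.33e-8	1.33e-9
PPA	15293	0.0011	0.0014	0.0005	-0.7477	0.7704	25	16732	1.70e-8	6.8e-10
GGG	12584	0.0023	0.0022	0.0016	0.1314	0.7640	19	13769	4.10e-8	2.16e-9
PAB	11901	0.0038	0.0037	0.0019	0.1374	0.6531	26	13021	7.26e-8	2.79e-9
PPY	13728	0.0027	0.0023	0.0013	0.6627	0.4962	26	15020	4.48e-8	1.72e-9
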