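protein	group	mean	sd	n
Gsk-3b	Sham	0.352	0.135	5
Gsk-3b	MCAO	0.421	0.163	5
Gsk-3b	DHI	0.359	0.169	5
Acta2	Sham	1.693	0.670	5
Acta2	MCAO	0.925	0.527	5
Acta2	DHI	1.338	0.762	5
Csnk1g1	Sham	0.350	0.048	5
Csnk1g1	MCAO	0.575	0.048	5
Csnk1g1	DHI	0.344	0.077	5
Apc	Sham	0.804	0.250	5
Apc	MCAO	0.371	0.051	5
Apc	DHI	0.743	0.163	5
Gpc4	Sham	0.330	0.188	5
Gpc4	MCAO	1.073	0.257	5
Gpc4	DHI	0.379	0.023	5
Ctbp2	Sham	0.749	0.480	5
Ctbp2	MCAO	1.103	0.463	5
Ctbp2	DHI	1.018	0.460	5
Akt1	Sham	0.404	0.187	5
Akt1	MCAO	0.700	0.155	5
Akt1	DHI	0.430	0.182	5
Sos1	Sham	0.247	0.083	5
Sos1	MCAO	0.765	0.050	5
Sos1	DHI	0.322	0.085	5
Prkaa1	Sham	0.733	0.353	5
Prkaa1	MCAO	0.282	0.075	5
Prkaa1	DHI	0.684	0.134	5
Eef2	Sham	0.288	0.084	5
Eef2	MCAO	0.558	0.091	5
Eef2	DHI	0.265	0.120	5
Flnc	Sham	0.370	0.021	5
Flnc	MCAO	1.477	0.276	5
Flnc	DHI	0.587	0.069	5
Rap1a	Sham	0.302	0.058	5
Rap1a	MCAO	0.521	0.020	5
Rap1a	DHI	0.322	0.038	5
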