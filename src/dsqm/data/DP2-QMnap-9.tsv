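#mode: nap
#penalty: -10.000
#provenance: DS-QMnap for HLA-DP2 binding prediction (9-mer binding core)
AA	p1	p2	p3	p4	p5	p6	p7	p8	p9
Ala	-0.248	0.092	0.059	0.054	0.015	-0.099	-0.007	0.007	0.176
Arg	-0.151	0.041	0.057	0.430	0.178	-0.037	0.293	-0.070	-0.425
Asn	-0.209	0.058	0.015	0.062	-0.053	-0.030	0.026	-0.062	0.208
Asp	-0.364	0.009	-0.087	-0.163	-0.172	-0.255	-0.212	-0.159	-0.013
Cys	-0.223	0.053	0.001	-0.016	-0.066	-0.098	-0.002	-0.069	0.224
Gln	-0.158	0.050	0.004	0.103	-0.025	-0.031	0.054	-0.108	0.207
Glu	-0.325	0.025	-0.105	-0.101	-0.177	-0.225	-0.194	-0.191	0.018
Gly	-0.321	0.054	0.009	0.022	0.001	-0.144	-0.046	-0.007	0.110
His	-0.070	0.157	0.053	0.055	-0.013	0.030	0.015	-0.069	0.012
Ile	-0.102	0.101	0.039	0.048	-0.016	-0.027	0.096	-0.048	0.069
Leu	-0.084	0.085	0.079	0.157	-0.014	-0.023	0.157	-0.031	0.073
Lys	-0.183	0.009	0.040	0.445	0.241	-0.032	0.430	-0.108	0.278
Met	-0.131	0.073	0.020	0.055	-0.056	-0.032	0.046	-0.091	0.236
Phe	0.157	0.111	0.122	0.118	0.012	0.157	0.082	0.002	-10.000
Pro	-0.555	-0.397	0.169	-0.470	0.157	-10.000	-10.000	0.157	-10.000
Ser	-0.321	0.040	0.009	-0.028	-0.070	-0.147	-0.083	-0.084	0.157
Thr	-0.251	0.083	0.068	-0.017	-0.058	-0.130	-0.019	-0.074	0.206
Trp	0.090	0.192	0.151	0.130	0.033	-0.191	0.203	-0.045	-10.000
Tyr	0.054	0.083	0.157	0.139	-0.021	0.103	0.086	-0.124	-10.000
Val	-0.140	0.110	0.108	0.051	-0.005	-0.056	0.025	-0.012	0.137
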