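#mode: npp
#penalty: -10.000
#provenance: DS-QMnpp for HLA-DP2 binding prediction (9-mer binding core)
AA	p1	p2	p3	p4	p5	p6	p7	p8	p9
Ala	-0.101	0.068	0.040	0.000	0.049	-0.079	-0.089	0.189	0.102
Arg	0.036	-0.017	0.030	0.411	0.445	0.073	0.379	-0.031	-0.753
Asn	-0.046	0.011	-0.122	0.009	-0.116	0.090	-0.037	-0.007	0.148
Asp	-0.263	-0.071	-0.493	-0.237	-0.403	-0.458	-0.408	-0.287	-0.167
Cys	-0.065	0.002	-0.173	-0.076	-0.146	-0.076	-0.081	-0.027	0.169
Gln	0.027	-0.003	-0.163	0.053	-0.048	0.086	0.006	-0.139	0.146
Glu	-0.208	-0.045	-0.559	-0.169	-0.417	-0.383	-0.380	-0.379	-0.124
Gly	-0.202	0.004	-0.143	-0.035	0.016	-0.187	-0.150	0.149	0.007
His	0.150	0.179	0.015	0.002	-0.018	0.235	-0.055	-0.027	-0.132
Ile	0.105	0.085	-0.036	-0.006	-0.025	0.097	0.071	0.033	-0.050
Leu	0.130	0.056	0.111	0.113	-0.021	0.107	0.167	0.081	-0.044
Lys	-0.009	-0.071	-0.031	0.428	0.597	0.083	0.592	-0.139	0.247
Met	0.064	0.037	-0.102	0.002	-0.123	0.083	-0.007	-0.091	0.187
Phe	0.469	0.101	0.269	0.070	0.043	0.542	0.050	0.177	-10.000
Pro	-0.531	-0.762	0.441	-0.572	0.394	-10.000	-10.000	0.621	-10.000
Ser	-0.202	-0.019	-0.143	-0.090	-0.157	-0.194	-0.206	-0.071	0.074
Thr	-0.105	0.054	0.071	-0.077	-0.126	-0.153	-0.107	-0.043	0.144
Trp	0.375	0.238	0.375	0.084	0.093	-0.302	0.238	0.041	-10.000
Tyr	0.324	0.054	0.395	0.093	-0.038	0.411	0.056	-0.187	-10.000
Val	0.052	0.099	0.218	-0.003	0.002	0.026	-0.039	0.137	0.047
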