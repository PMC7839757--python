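band	mortality_male	mortality_female	relapse
0	0.050	0.040	0.000
1-4	0.006	0.005	0.000
5-9	0.001	0.001	0.000
10-14	0.001	0.001	0.002
15-19	0.001	0.002	0.002
20-24	0.004	0.006	0.004
25-29	0.010	0.012	0.004
30-34	0.017	0.016	0.005
35-39	0.021	0.016	0.005
40-44	0.028	0.016	0.007
45-49	0.025	0.016	0.007
50-54	0.024	0.020	0.009
55-59	0.029	0.016	0.009
60-64	0.052	0.019	0.010
65-69	0.056	0.025	0.010
70-74	0.066	0.024	0.012
75-79	0.071	0.036	0.012
80-84	0.099	0.067	0.012
85-89	0.118	0.107	0.012
90-94	0.190	0.091	0.012
95+	0.190	0.170	0.012
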