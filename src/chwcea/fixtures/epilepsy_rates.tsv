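band	mortality_nonadherent	mortality_adherent	remission_male	remission_female
0-5	0.030	0.006	0.160	0.305
6-12	0.054	0.011	0.033	0.066
13-18	0.019	0.004	0.045	0.004
19-28	0.043	0.009	0.093	0.013
29-49	0.060	0.012	0.000	0.031
50+	0.074	0.015	0.020	0.065
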