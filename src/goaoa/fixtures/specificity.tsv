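algorithm	base_Brain_T21	base_Breastcancer4	base_BreastEW	base_CongressEW1	base_Exactly	base_leuk1	base_M-of-n3	base_PenglungEW3	base_SonarEW2	base_Vote3	base_WineEW1	zoo
BPSO	1.000	0.980	1.000	0.970	1.000	1.000	1.000	1.000	1.000	1.000	1.000	1.000
WOA	1.000	0.940	0.976	0.970	1.000	1.000	1.000	1.000	1.000	1.000	1.000	1.000
HHO	1.000	0.980	1.000	0.970	1.000	1.000	1.000	1.000	1.000	1.000	1.000	1.000
SSA	1.000	1.000	0.976	0.970	1.000	0.900	1.000	1.000	1.000	1.000	1.000	1.000
GO	0.750	0.980	0.951	0.970	0.969	0.900	0.985	1.000	1.000	1.000	1.000	1.000
AOA	1.000	0.980	0.976	0.970	1.000	1.000	1.000	1.000	1.000	1.000	1.000	1.000
GOAOA	1.000	0.980	0.976	0.970	1.000	1.000	1.000	1.000	1.000	1.000	1.000	1.000
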