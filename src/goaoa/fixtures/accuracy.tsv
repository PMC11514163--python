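algorithm	base_Brain_T21	base_Breastcancer4	base_BreastEW	base_CongressEW1	base_Exactly	base_leuk1	base_M-of-n3	base_PenglungEW3	base_SonarEW2	base_Vote3	base_WaveformEW9	base_WineEW1	zoo
BPSO	1.000	0.993	0.991	0.966	1.000	1.000	1.000	1.000	1.000	1.000	0.772	1.000	1.000
WOA	1.000	0.971	0.983	0.966	1.000	1.000	1.000	1.000	1.000	1.000	0.747	1.000	1.000
HHO	1.000	0.993	0.983	0.966	1.000	1.000	1.000	1.000	1.000	1.000	0.774	1.000	1.000
SSA	0.900	0.993	0.991	0.977	1.000	0.933	1.000	1.000	1.000	1.000	0.758	1.000	1.000
GO	0.800	0.986	0.965	0.954	0.990	0.933	0.975	1.000	0.976	1.000	0.740	1.000	1.000
AOA	1.000	0.993	0.983	0.966	1.000	1.000	1.000	1.000	1.000	1.000	0.770	1.000	1.000
GOAOA	1.000	0.993	0.991	0.966	1.000	1.000	1.000	1.000	1.000	1.000	0.774	1.000	1.000
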