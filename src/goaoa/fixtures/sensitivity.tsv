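algorithm	base_Brain_T21	base_Breastcancer4	base_BreastEW	base_CongressEW1	base_Exactly	base_leuk1	base_M-of-n3	base_PenglungEW3	base_SonarEW2	base_Vote3	base_WaveformEW9	base_WineEW1	zoo
BPSO	1.000	1.000	1.000	0.963	1.000	1.000	1.000	1.000	1.000	1.000	0.772	1.000	1.000
WOA	1.000	0.989	1.000	0.963	1.000	1.000	1.000	1.000	1.000	1.000	0.722	1.000	1.000
HHO	1.000	1.000	1.000	0.963	1.000	1.000	1.000	1.000	1.000	1.000	0.778	1.000	1.000
SSA	1.000	1.000	1.000	0.982	1.000	1.000	1.000	1.000	1.000	1.000	0.772	1.000	1.000
GO	1.000	0.989	1.000	0.944	1.000	1.000	0.970	1.000	0.952	1.000	0.746	1.000	1.000
AOA	1.000	1.000	1.000	0.963	1.000	1.000	1.000	1.000	1.000	1.000	0.775	1.000	1.000
GOAOA	1.000	1.000	1.000	0.963	1.000	1.000	1.000	1.000	1.000	1.000	0.781	1.000	1.000
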