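age,annual_rate
60,0.006
65,0.009
70,0.015
75,0.025
80,0.042
85,0.072
90,0.120
95,0.200
100,0.320
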