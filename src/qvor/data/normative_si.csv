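percentile,left_si,right_si,bilateral_si
5,0.202,0.182,0.141
10,0.224,0.225,0.181
25,0.287,0.254,0.224
50,0.354,0.325,0.283
75,0.412,0.390,0.348
90,0.530,0.529,0.451
95,0.584,0.610,0.540
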