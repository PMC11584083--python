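age_weeks,weight_g
0,47.68
1,151.76
2,352.37
3,613.21
4,1033.27
5,1607.70
6,2193.10
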