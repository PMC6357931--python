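patient,mslope,mlength_m_per_s,doppler_m_per_s
1,3.12,0.29,0.22
2,1.18,0.26,0.36
3,1.47,0.16,0.28
4,2.34,0.16,0.15
5,3.08,0.22,0.37
6,1.64,0.20,0.22
7,2.06,0.35,0.19
8,5.48,0.43,0.39
9,3.66,0.41,0.52
10,0.79,0.15,0.22
11,0.37,0.10,0.20
12,3.05,0.36,0.25
13,0.87,0.14,0.18
14,2.61,0.32,0.20
15,1.01,0.11,0.20
16,2.88,0.21,0.21
17,0.97,0.11,0.19
18,1.94,0.22,0.19
19,1.29,0.14,0.17
20,1.98,0.19,0.30
21,2.56,0.23,0.25
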