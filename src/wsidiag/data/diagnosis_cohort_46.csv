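scan_id,D1,D2,D3,D4,D5,D6,D7,D8,D9,c_tissue_pct,model
1,C,C,C,C,C,C,C,C,C,13.35,C
2,C,C,C,IHC,C,C,C,C,C,21.77,C
3,C,C,C,C,C,C,C,C,C,13.78,C
4,C,C,C,C,C,IHC,C,C,C,10.9,C
5,C,C,C,C,C,C,C,C,C,35.16,C
6,C,C,C,C,C,C,C,C,C,34.8,C
7,C,C,C,C,C,C,C,C,C,46.16,C
8,C,C,C,C,C,C,C,C,C,46.78,C
9,C,C,C,C,C,C,C,C,C,24.83,C
10,C,IHC,NC,C,NC,NC,NC,IHC,IHC,1.87,IHC
11,C,C,C,C,C,C,C,C,C,33.22,C
12,C,C,C,C,C,C,C,C,C,3.9,IHC
13,C,C,IHC,IHC,NC,IHC,IHC,C,C,0.33,NC
14,NC,NC,NC,NC,NC,NC,NC,IHC,NC,0.0,NC
15,C,NC,IHC,IHC,IHC,NC,IHC,IHC,IHC,0.15,NC
16,NC,NC,NC,NC,NC,NC,NC,NC,NC,0.06,NC
17,C,C,C,C,C,C,C,C,C,25.04,C
18,C,C,C,C,C,C,C,C,C,46.0,C
19,IHC,IHC,NC,IHC,NC,IHC,NC,IHC,IHC,2.16,IHC
20,IHC,IHC,NC,IHC,NC,NC,NC,NC,IHC,0.09,NC
21,IHC,IHC,NC,IHC,NC,IHC,IHC,IHC,IHC,1.33,IHC
22,C,C,C,C,C,C,C,C,C,8.51,C
23,C,C,C,C,C,C,C,C,C,69.31,C
24,IHC,C,C,C,C,C,C,C,C,2.55,IHC
25,IHC,C,C,IHC,C,C,C,C,C,2.46,IHC
26,IHC,C,C,C,C,C,C,C,C,3.49,IHC
27,C,C,C,C,C,C,C,C,C,5.87,IHC
28,C,C,C,C,C,C,C,IHC,C,69.49,C
29,C,C,C,C,C,C,C,C,C,54.05,C
30,IHC,C,IHC,C,C,C,C,C,C,8.76,C
31,C,C,C,C,C,C,C,C,C,13.38,C
32,C,C,C,C,C,C,C,C,C,10.02,C
33,IHC,IHC,NC,IHC,NC,NC,NC,IHC,NC,6.42,IHC
34,C,C,C,C,C,C,C,C,C,29.68,C
35,C,C,C,C,C,C,C,C,C,55.96,C
36,C,C,C,C,C,C,C,C,C,37.92,C
37,C,C,C,C,C,C,C,C,C,10.21,C
38,C,C,C,C,C,C,C,C,C,27.6,C
39,C,C,C,C,C,C,C,C,C,14.54,C
40,C,C,C,C,C,C,C,C,C,32.48,C
41,NC,NC,NC,NC,NC,NC,NC,NC,NC,0.39,NC
42,NC,NC,NC,IHC,NC,NC,NC,IHC,IHC,5.13,IHC
43,C,C,C,C,C,C,C,C,C,21.11,C
44,IHC,NC,IHC,NC,IHC,IHC,NC,IHC,IHC,0.13,NC
45,NC,NC,NC,NC,NC,NC,NC,NC,NC,0.49,NC
46,NC,NC,NC,NC,NC,NC,NC,NC,IHC,0.4,NC
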