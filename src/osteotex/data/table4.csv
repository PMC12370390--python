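specimen_id,ash_density,e_measured,e_powerlaw,residual
1,0.74,2.4637,2.019603,0.197276
2,0.71,1.6840,2.009026,0.105642
3,0.5,1.7633,1.921608,0.025039
4,0.84,2.1920,2.052342,0.019527
5,0.63,0.5100,1.978786,2.15712
6,0.74,2.2376,2.019603,0.047562
7,0.42,2.3394,1.879568,0.211446
8,0.59,2.0377,1.962386,0.00568
9,0.84,2.4293,2.052342,0.142135
10,1.45,2.4059,2.199528,0.042598
11,1.97,2.6393,2.286734,0.124338
12,1.35,2.4084,2.179677,0.052356
13,1.25,2.6806,2.158498,0.272601
14,1.71,1.94991,2.246037,0.087691
15,1.5,2.80716,2.209008,0.357785
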