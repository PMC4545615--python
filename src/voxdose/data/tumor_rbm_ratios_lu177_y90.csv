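patient_id,ratio_lu,ratio_y,percent_difference
7,1.88,2.13,13
10,5.72,6.54,14
11,8.84,9.78,11
12,5.08,7.27,43
13,4.33,4.33,0
14,5.26,6.37,21
15,1.49,2.29,54
16,0.68,1.06,56
17,1.46,2.02,39
18,9.45,8.87,-6
19,5.11,4.97,-3
20,0.64,0.99,54
21,10.91,13.72,26
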