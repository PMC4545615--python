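patient_id,administered_activity_GBq,tumor_volume_mL,ad_tumor_3d_Gy,ad_rbm_3d_Gy,ad_tumor_sphere_Gy,ad_rbm_blood_Gy,ad_rbm_cranium_Gy,grade_thrombocytopenia,grade_leucopenia
7,6.2,14,0.73,0.39,0.71,,,0,0
10,7.4,70,2.94,0.51,2.67,,,4,1
11,7.4,44,2.53,0.29,2.47,,,0,0
12,7.4,386,1.54,0.30,1.47,,,0,0
13,7.4,23,0.51,0.12,0.51,,,0,0
14,4.0,23,3.70,0.70,3.72,,,1,0
15,5.9,285,0.86,0.58,0.83,,,1,0
16,4.6,121,0.66,0.97,0.64,,,3,2
17,4.5,65,0.63,0.43,0.62,,,2,0
18,2.5,104,4.52,0.47,4.44,,,0,2
19,7.4,141,1.45,0.28,1.38,,,0,0
20,5.6,723,0.46,0.72,0.45,,,1,0
21,5.6,154,2.47,0.23,2.45,,,0,0
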