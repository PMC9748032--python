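subject_id,section,initial_score,manual_tv_cc,manual_tmd_cm,auto_tv_cc,auto_tmd_cm,rescored_score
A1,A,3,0.46,0.98,0.39,1.67,5
A2,A,3,0.75,0.85,1.16,1.72,5
A3,A,3,0.70,0.80,0.75,1.68,5
A4,A,3,0.36,0.65,0.67,1.65,5
B1,B,4,0.72,0.92,1.21,1.60,5
B2,B,4,1.02,1.16,1.35,1.67,5
B3,B,4,0.53,1.29,1.20,2.19,5
B4,B,4,1.34,1.40,1.61,2.31,5
B5,B,4,0.65,1.01,0.63,1.53,5
B6,B,4,0.90,1.26,1.90,2.20,5
B7,B,4,0.65,1.13,0.68,1.75,5
B8,B,4,0.29,0.85,0.42,1.64,5
B9,B,4,1.20,0.95,1.52,1.90,5
B10,B,4,1.65,1.10,1.48,2.15,5
B11,B,4,0.90,0.89,1.80,2.10,5
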