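score,manual_tv_mean,manual_tv_sd,auto_tv_mean,auto_tv_sd,manual_tmd_mean,manual_tmd_sd,auto_tmd_mean,auto_tmd_sd
3,0.36,0.21,0.49,0.31,0.73,0.12,1.36,0.28
4,0.74,0.44,0.99,0.58,1.01,0.19,1.67,0.38
5,0.93,0.39,1.05,0.78,1.14,0.25,1.97,0.67
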