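# Default interference-bin exclusion list: the suppressed-water region [4.70, 4.90),
# 20 bins at 0.01 ppm. Edit or replace via --exclude-bins FILE.
4.70
4.71
4.72
4.73
4.74
4.75
4.76
4.77
4.78
4.79
4.80
4.81
4.82
4.83
4.84
4.85
4.86
4.87
4.88
4.89
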