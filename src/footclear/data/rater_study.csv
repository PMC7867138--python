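pedestrian,manual_mean_mm,manual_sd_mm,manual_rms_mm,auto_rms_mm
1,7.76,0.57,0.51,0.56
2,16.33,3.19,2.85,3.26
3,6.04,2.18,1.95,0.86
4,13.52,1.98,1.77,7.23
5,1.36,0.77,0.69,0.50
6,1.79,1.76,5.54,5.66
7,7.28,6.19,1.58,0.67
8,8.46,2.28,2.04,2.09
9,9.89,5.04,4.34,11.34
10,16.61,2.14,1.91,7.40
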