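# Measured and regression-estimated air kerma free-in-air (K_air, mGy) at
# isocenter for seven CBCT protocols at each tube potential, with the printed
# signed percent difference. These pairs drive the K_air-vs-mAs dose models.
protocol,kvp,framerate_s,cumulative_mAs,estimate_mGy,measured_mGy,printed_diff_pct
1,80,3,338,5.8,5.7,2.5
2,80,7,788,13.3,13.3,0.2
3,80,11,1238,20.8,20.9,0.6
5,80,15,405,7.0,7.0,0.2
6,80,15,810,13.7,13.6,0.6
7,80,15,1170,19.7,19.6,0.2
8,80,15,1688,28.3,28.2,0.3
1,140,3,338,29.0,27.4,5.8
2,140,7,788,64.5,63.7,1.2
3,140,11,1238,99.9,100.2,0.2
5,140,15,405,34.3,34.9,1.5
6,140,15,810,66.3,66.2,0.1
7,140,15,1170,94.6,94.8,0.2
8,140,15,1688,135.4,135.2,0.1
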