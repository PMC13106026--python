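# Eight pulsed-fluoroscopy CBCT protocols (60 s, 360 deg rotation) used for the
# dose calibration; protocol 8 at 140 kVp is the clinical Pelvis Large Protocol.
protocol,framerate_s,ma,pulse_ms,cumulative_mAs
1,3,75,25,338
2,7,75,25,788
3,11,75,25,1238
4,15,10,10,90
5,15,45,10,405
6,15,45,20,810
7,15,65,20,1170
8,15,75,25,1688
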