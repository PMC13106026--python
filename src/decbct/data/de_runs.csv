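# Dual-energy CBCT run matrix: cumulative mAs of the 80 and 140 kVp scans and
# the shared framerate, plus the published absolute/relative K_air of each run.
# Run 1 is the single-energy 140 kVp clinical reference (Pelvis Large Protocol).
run,mAs_80,mAs_140,framerate_s,kair_mGy,kair_pct
1,,1688,15,134,100
2,4046,833,15,134,100
3,4092,825,11,134,100
4,3250,653,15,107,80
5,3253,660,11,108,80
6,2433,504,15,82,61
7,2442,495,11,82,61
8,2440,483,7,81,60
9,2430,488,3,81,60
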