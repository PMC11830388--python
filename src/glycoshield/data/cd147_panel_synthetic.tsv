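# SYNTHETIC stand-in for a 13-clone single-target antibody panel.
# Epitope-position categories follow the published cross-blocking scheme
# (clones 6, 7, 12 membrane-proximal; 1, 2, 11 membrane-distal; the rest
# intermediate); the Kd values are generator choices log-spaced over
# 0.1-100 nM, not measured affinities.
antibody	kd_nm	epitope_position
1	0.1	distal
2	0.178	distal
3	0.316	intermediate
4	0.562	intermediate
5	1	intermediate
6	1.78	proximal
7	3.16	proximal
8	5.62	intermediate
9	10	intermediate
10	17.8	intermediate
11	31.6	distal
12	56.2	proximal
13	100	intermediate
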