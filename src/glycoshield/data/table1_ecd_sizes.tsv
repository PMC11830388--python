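# Extracellular-domain sizes (Å) of 15 surface proteins, with whether every
# tested epitope was shielded ("affected") or at least one epitope escaped
# shielding ("non_affected").
protein	ecd_size_angstrom	group
CD9	40.5	affected
CD47	44.6	affected
CD59	31.7	affected
CD81	39.2	affected
CD98	72.0	affected
CD147	71.5	affected
CD321	82.9	affected
CD46	112.8	non_affected
CD49b	157.9	non_affected
CD49d	108.5	non_affected
CD49e	126.3	non_affected
CD51	130.9	non_affected
CD155	115.6	non_affected
SIRPa	124.1	non_affected
HLA-I	70.2	non_affected
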