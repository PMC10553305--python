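station_id,particles_per_L
S01,0.2815
S02,0.2581
S03,1.2125
S04,5.0181
S05,1.7942
S06,3.2425
S07,2.1931
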