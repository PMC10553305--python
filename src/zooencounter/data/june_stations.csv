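station_id,particles_per_L
S01,7.0
S02,12.1034
S03,23.9718
S04,8.7439
S05,19.0363
S06,7.0
S07,9.1927
S08,25.867
S09,12.3099
S10,11.8077
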