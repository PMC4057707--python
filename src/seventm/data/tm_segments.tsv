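helix	generic_start	generic_end
TM1	101	134
TM2	201	234
TM3	308	341
TM4	401	434
TM5	501	534
TM6	601	634
TM7	701	734
H8	801	812
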