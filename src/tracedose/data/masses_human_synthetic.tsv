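# SYNTHETIC human organ-mass fixture (reference-adult magnitudes, grams).
organ	mass_g
eyes	15.0
liver	1800.0
kidneys	310.0
spleen	180.0
muscle	28000.0
total_body	73000.0
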