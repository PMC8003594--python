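# SYNTHETIC mouse S-value fixture for iodine-131 (self-dose terms).
# Magnitudes follow first-principles local beta deposition
# (~1.1e-4 J per MBq·h, mean beta energy 0.192 MeV) scaled by an
# absorbed fraction ~0.7 for sub-gram organs. Template for transcribing
# published murine S-factor tables; NOT measured or published values.
source_organ	target_organ	s_value_gy_per_mbq_h
tumor	tumor	0.19
eyes	eyes	3.85
liver	liver	0.064
kidneys	kidneys	0.22
spleen	spleen	0.77
muscle	muscle	0.0096
total_body	total_body	0.0035
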