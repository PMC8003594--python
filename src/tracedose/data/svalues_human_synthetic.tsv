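# SYNTHETIC human S-value fixture for iodine-131 (self-dose terms).
# Magnitudes follow local beta deposition (~1.1e-4 J per MBq·h) over
# reference-adult organ masses with absorbed fraction ~0.9; template for
# transcribing published phantom S-factors. NOT measured or published values.
source_organ	target_organ	s_value_gy_per_mbq_h
eyes	eyes	6.6e-3
liver	liver	5.5e-5
kidneys	kidneys	3.2e-4
spleen	spleen	5.5e-4
muscle	muscle	3.5e-6
total_body	total_body	2.4e-6
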