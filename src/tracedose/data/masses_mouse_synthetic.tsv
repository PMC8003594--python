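# SYNTHETIC mouse organ-mass fixture (typical adult C57BL/6-sized mouse).
organ	mass_g
tumor	0.4
eyes	0.02
liver	1.2
kidneys	0.35
spleen	0.1
muscle	8.0
total_body	25.0
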