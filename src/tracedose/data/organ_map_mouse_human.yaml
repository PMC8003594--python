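# Mouse -> human organ-label mapping for extrapolation.
# The tumor has no human counterpart and is deliberately absent.
eyes: eyes
liver: liver
kidneys: kidneys
spleen: spleen
muscle: muscle
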