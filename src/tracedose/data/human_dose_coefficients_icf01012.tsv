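# Published human dose coefficients for [131I]ICF01012 extrapolated with
# OLINDA phantom S-values: absorbed dose per unit injected activity
# (Gy/GBq) and the printed absorbed dose for a standard 3.7 GBq
# therapeutic administration (Gy). Used as *input* to verify the
# dose-at-activity arithmetic of the reporting stage.
organ	dose_gy_per_gbq	printed_dose_gy_at_3p7_gbq
adrenals	0.006	0.023
brain	0.007	0.025
gall_bladder	0.010	0.037
lower_large_intestine	0.021	0.079
small_intestine	0.048	0.176
stomach	0.043	0.159
upper_large_intestine	0.021	0.078
heart	0.012	0.044
kidneys	0.055	0.203
liver	0.064	0.238
lungs	0.028	0.105
muscle	0.003	0.009
ovaries	0.007	0.026
pancreas	0.008	0.028
red_marrow	0.003	0.010
skin	0.001	0.004
spleen	0.062	0.229
testes	0.012	0.044
thymus	0.002	0.007
thyroid	0.044	0.163
urinary_bladder	0.184	0.682
total_body	0.006	0.021
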