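modality,metric,max_sd
CBCT,hu_air,3.1
CBCT,hu_polyethylene,4.5
CBCT,hu_water,7.9
CBCT,hu_acrylic,6.1
CBCT,hu_bone,29.1
CBCT,uniformity_hu,11.0
CBCT,distance_mm,0.5
CT,uniformity_hu,0.7
CT,low_contrast_cnr,0.21
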