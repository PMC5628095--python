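allometry_key,form,coeff_a,exponent_c,dbh_min_cm,dbh_max_cm,source
broadleaf_generic,power_law,0.12,2.4,5,80,synthetic generic temperate broadleaf power law (implementation default; not a published species equation)
conifer_generic,power_law,0.10,2.4,5,80,synthetic generic temperate conifer power law (implementation default; not a published species equation)
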