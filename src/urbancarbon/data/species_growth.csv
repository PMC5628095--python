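class_id,label,family,A,k,p,b,residual_error_cm,canopy_fraction_pct,allometry_key
1,Acer campestre; Acer platanoides; Acer sp.,saturating,202.9173,0.0019,0.7992,,5.48,12.9,broadleaf_generic
2,Aesculus hypocastanum,saturating,175.5828,0.0042,0.8958,,6.57,13.4,broadleaf_generic
3,Fagus sylvatica,saturating,202.9173,0.0019,0.7992,,6.15,10.4,broadleaf_generic
4,Pinus sylvestris,gompertz,135.4549,0.0152,,3.1143,4.74,11.3,conifer_generic
5,Platanus hispanica,saturating,170.5888,0.0047,0.913,,4.95,1.9,broadleaf_generic
6,Populus nigra; Populus alba,saturating,93.5402,0.0152,1.1518,,10.77,1.8,broadleaf_generic
7,Quercus robur; Quercus rubra; Quercus sp.,gompertz,70.2797,0.0289,,2.8528,4.03,8.6,broadleaf_generic
8,Tilia cordata; Tilia x vulgaris; Tilia platyphyllos,saturating,56.4678,0.0182,1.053,,5.71,13.2,broadleaf_generic
9,Betula pendula,saturating,199.1001,0.0029,0.8865,,4.48,,broadleaf_generic
10,Robinia pseudoacacia,gompertz,116.6451,0.0198,,3.1542,5.40,,broadleaf_generic
mix,Mix of dominant species,mix,,,,,,26.5,mix
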