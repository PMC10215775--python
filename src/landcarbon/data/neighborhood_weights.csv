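scenario,cultivated,forest,grassland,water,construction,unused
s1-trend,0.50,0.77,0.50,0.58,0.83,0.50
s2-eco,0.50,0.82,0.75,0.58,0.70,0.60
s3-comprehensive,0.50,0.77,0.75,0.58,0.77,0.60
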