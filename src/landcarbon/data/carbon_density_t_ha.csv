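class,c_above,c_below,c_soil,c_dead
cultivated,1.31,0.73,11.65,0
forest,40.41,10.45,42.75,2.62
grassland,2.55,8.31,15.1,0.85
water,0,0,0,0
construction,0,0,0,0
unused,0,0,4.2,0
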