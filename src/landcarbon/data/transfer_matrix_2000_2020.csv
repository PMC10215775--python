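class,cultivated,forest,grassland,water,construction,unused,Total
cultivated,3426.40,218.07,196.14,25.74,387.23,0.80,4254.38
forest,230.43,8765.48,441.07,40.69,119.74,1.79,9599.20
grassland,268.31,456.62,5154.64,19.52,236.11,6.52,6141.72
water,17.92,4.07,6.27,420.81,24.26,0.32,473.65
construction,32.26,11.51,10.47,4.20,425.58,0.19,484.21
unused,0.99,1.17,4.18,0.51,0.13,60.91,67.89
Total,3976.31,9456.92,5812.77,511.47,1193.05,70.53,21021.05
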