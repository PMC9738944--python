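class_code,class_name,c_above,c_below,c_soil,c_dead
1,farmland,13.05,7.30,103.48,2.32
2,forest,20.36,67.50,170.00,7.80
3,grassland,0.82,0.87,199.84,1.28
4,aquatic,1.02,1.34,83.63,0.48
5,settlement,0.07,1.63,205.07,0.35
6,other,0.74,0.93,90.90,0.36
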