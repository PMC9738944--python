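class_code,class_name,area_2010,area_2020,area_2030,area_2050
1,farmland,49275,48289,47043,49827
2,forest,94833,93027,92463,9012
3,grassland,30821,31184,30495,29749
4,aquatic,485,1189,1056,1257
5,settlement,642,2378,2616,2718
6,other,37,31,29,28
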