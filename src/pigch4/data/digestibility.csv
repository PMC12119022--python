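ingredient,animal_class,d_om,d_cp,d_cf,d_starch_sugar
barley,growing,0.86,0.80,0.55,0.999
barley,sow,0.87,0.82,0.55,0.999
wheat,growing,0.90,0.87,0.55,0.999
wheat,sow,0.91,0.89,0.55,0.999
rye,growing,0.87,0.80,0.50,0.999
rye,sow,0.88,0.82,0.50,0.999
oats,growing,0.76,0.78,0.80,0.999
oats,sow,0.80,0.80,0.80,0.999
sugar beet pulp,growing,0.80,0.60,0.45,0.999
sugar beet pulp,sow,0.86,0.64,0.45,0.999
soy hulls,growing,0.62,0.58,0.55,0.999
soy hulls,sow,0.68,0.62,0.55,0.999
wheat bran,growing,0.64,0.74,0.60,0.999
wheat bran,sow,0.68,0.76,0.60,0.999
soybean meal,growing,0.87,0.90,0.70,0.999
soybean meal,sow,0.88,0.91,0.70,0.999
sunflower meal,growing,0.75,0.84,0.75,0.999
sunflower meal,sow,0.77,0.85,0.75,0.999
potato protein,growing,0.92,0.93,0.80,0.999
potato protein,sow,0.93,0.94,0.80,0.999
fish meal,growing,0.90,0.92,0.85,0.999
fish meal,sow,0.91,0.93,0.85,0.999
vegetable oil,growing,0.90,0.80,0.90,0.999
vegetable oil,sow,0.92,0.80,0.90,0.999
l-lysine 70,growing,0.98,0.98,0.90,0.999
l-lysine 70,sow,0.98,0.98,0.90,0.999
dl-methionine 99,growing,0.98,0.98,0.90,0.999
dl-methionine 99,sow,0.98,0.98,0.90,0.999
l-threonine 98.5,growing,0.98,0.98,0.90,0.999
l-threonine 98.5,sow,0.98,0.98,0.90,0.999
l-tryptophan 98,growing,0.98,0.98,0.90,0.999
l-tryptophan 98,sow,0.98,0.98,0.90,0.999
l-valine 96.5,growing,0.98,0.98,0.90,0.999
l-valine 96.5,sow,0.98,0.98,0.90,0.999
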