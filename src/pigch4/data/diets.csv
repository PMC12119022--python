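category,diet,ingredient,proportion_asfed
weaned,average,barley,0.2000
weaned,average,wheat,0.5611
weaned,average,soybean meal,0.1400
weaned,average,potato protein,0.0250
weaned,average,fish meal,0.0100
weaned,average,vegetable oil,0.0180
weaned,average,l-lysine 70,0.0110
weaned,average,dl-methionine 99,0.0023
weaned,average,l-threonine 98.5,0.0030
weaned,average,l-tryptophan 98,0.0009
weaned,average,l-valine 96.5,0.0015
weaned,average,monocalcium phosphate,0.0030
weaned,average,calcium carbonate,0.0152
weaned,average,salt,0.0070
weaned,average,vitamin mineral premix,0.0020
grower_finisher,average,barley,0.2700
grower_finisher,average,wheat,0.4043
grower_finisher,average,rye,0.1000
grower_finisher,average,soybean meal,0.1670
grower_finisher,average,sunflower meal,0.0200
grower_finisher,average,vegetable oil,0.0080
grower_finisher,average,l-lysine 70,0.0045
grower_finisher,average,dl-methionine 99,0.0007
grower_finisher,average,l-threonine 98.5,0.0020
grower_finisher,average,monocalcium phosphate,0.0030
grower_finisher,average,calcium carbonate,0.0145
grower_finisher,average,salt,0.0040
grower_finisher,average,vitamin mineral premix,0.0020
gestating_sow,average,barley,0.4720
gestating_sow,average,wheat,0.2465
gestating_sow,average,rye,0.1000
gestating_sow,average,sugar beet pulp,0.0250
gestating_sow,average,soy hulls,0.0810
gestating_sow,average,soybean meal,0.0520
gestating_sow,average,vegetable oil,0.0050
gestating_sow,average,monocalcium phosphate,0.0020
gestating_sow,average,calcium carbonate,0.0125
gestating_sow,average,salt,0.0020
gestating_sow,average,vitamin mineral premix,0.0020
lactating_sow,average,barley,0.1820
lactating_sow,average,wheat,0.4992
lactating_sow,average,rye,0.1000
lactating_sow,average,sugar beet pulp,0.0250
lactating_sow,average,soybean meal,0.1530
lactating_sow,average,vegetable oil,0.0050
lactating_sow,average,l-lysine 70,0.0050
lactating_sow,average,dl-methionine 99,0.0010
lactating_sow,average,l-threonine 98.5,0.0015
lactating_sow,average,monocalcium phosphate,0.0080
lactating_sow,average,calcium carbonate,0.0145
lactating_sow,average,salt,0.0038
lactating_sow,average,vitamin mineral premix,0.0020
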