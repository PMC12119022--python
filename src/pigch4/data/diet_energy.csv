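category,diet,fu_per_kg_asfed
weaned,average,1.12
weaned,sugar_beet_pulp,1.087015
weaned,wheat_bran,1.095816
weaned,oat,1.094340
weaned,wheat,1.129346
grower_finisher,average,1.07
grower_finisher,sugar_beet_pulp,1.035281
grower_finisher,wheat_bran,1.044263
grower_finisher,oat,1.040161
grower_finisher,wheat,1.078278
lactating_sow,average,1.05
lactating_sow,sugar_beet_pulp,1.027625
lactating_sow,wheat_bran,1.029045
lactating_sow,oat,1.032055
lactating_sow,wheat,1.054958
gestating_sow,average,0.99
gestating_sow,sugar_beet_pulp,0.944055
gestating_sow,wheat_bran,0.949828
gestating_sow,oat,0.957814
gestating_sow,wheat,0.998096
gestating_sow,soy_hull,0.813879
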