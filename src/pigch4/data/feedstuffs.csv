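name,dm,om,cp,cf,starch,sugar,rf,indf,nsp,snsp,ash
barley,854,979,109,31,604,21,214,28,186,56,21
sugar beet pulp,898,946,88,16,0,59,783,34,700,290,54
fish meal,929,848,772,98,0,0,0,0,0,0,152
oats,853,974,114,59,471,18,313,118,232,39,26
potato protein,900,977,859,22,0,0,96,1,0,0,23
rye,857,984,95,20,613,32,224,29,152,43,16
soy hulls,875,950,108,24,7,19,792,10,680,126,50
soybean meal,876,926,487,29,33,93,284,6,217,63,74
vegetable oil,995,1000,0,1000,0,0,0,0,0,0,0
sunflower meal,900,925,388,27,17,56,437,156,255,10,75
wheat,856,983,113,24,670,19,157,22,119,29,17
wheat bran,874,936,168,52,220,37,459,97,374,30,64
monocalcium phosphate,990,0,0,0,0,0,0,0,0,0,1000
calcium carbonate,990,0,0,0,0,0,0,0,0,0,1000
salt,990,0,0,0,0,0,0,0,0,0,1000
vitamin mineral premix,990,0,0,0,0,0,0,0,0,0,1000
l-lysine 70,990,838.4,838.4,0,0,0,0,0,0,0,161.6
dl-methionine 99,990,580.8,580.8,0,0,0,0,0,0,0,419.2
l-threonine 98.5,990,723.9,723.9,0,0,0,0,0,0,0,276.1
l-tryptophan 98,990,840.2,840.2,0,0,0,0,0,0,0,159.8
l-valine 96.5,990,721.1,721.1,0,0,0,0,0,0,0,278.9
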