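intervention,classification,icer,halys,total_cost,first3y_cost,offsets,net_cost,evidence_bmi
Alcohol price increase: uniform volumetric tax,regulatory,,471165,32000000,25000000,-4800000000,-4800000000,low
Sugar-sweetened beverages tax - 20%,regulatory,,175300,120000000,12000000,-1700000000,-1600000000,low
Restricting television advertising of unhealthy foods,regulatory,,88396,6000000,1500000,-784000000,-778000000,low
Package size cap on sugar-sweetened beverages,regulatory,,73883,210000000,144000000,-751000000,-541000000,low
Supermarket shelf tags on healthier products,program,,72532,9000000,9000000,-647000000,-638000000,low
Menu kilojoule labelling on fast food,regulatory,,63492,170000000,37000000,-672000000,-502000000,low
School-based intervention to reduce sedentary behaviour,program,,61989,15000000,14000000,-661000000,-646000000,medium
School-based intervention to increase physical activity,program,,60780,10000000,10000000,-641000000,-631000000,medium
Restrictions on price promotions of sugar-sweetened beverages,regulatory,,48336,17000000,5000000,-498000000,-481000000,low
Reformulation to reduce sugar in sugar-sweetened beverages,regulatory,,28981,45000000,31000000,-295000000,-251000000,low
National mass media campaign related to sugar-sweetened beverages,program,,13958,31000000,31000000,-157000000,-127000000,low
Reformulation in response to the Health Star Rating system,regulatory,1728,4207,46000000,31000000,-42000000,5000000,low
Financial incentives for weight loss provided by private health insurers,program,7376,140110,1700000000,1600000000,-692000000,1000000000,high
Fuel excise: 10c per litre increase,regulatory,7684,237,4000000,4000000,-2000000,2000000,low
Community-based interventions,program,8155,51792,878000000,878000000,-452000000,426000000,high
Workplace intervention to reduce sedentary behaviour,program,28703,7492,269000000,269000000,-54000000,215000000,low
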