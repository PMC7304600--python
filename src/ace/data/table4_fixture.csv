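intervention,evidence_bmi,evidence_pa_diet,equity,accept_public,accept_government,accept_industry,feasibility,sustainability,icer_printed,ce_rank
Community-based interventions,high,n/a,neutral,high,high,high,medium,medium,8155,15
Financial incentives for weight loss provided by private health insurers,high,n/a,negative,medium,high,medium,high,medium,7896,13
School-based intervention to reduce sedentary behaviour,medium,medium,positive,high,high,high,high,medium,,7
School-based intervention to increase physical activity,medium,medium,positive,high,high,high,high,medium,,8
Reformulation in response to the Health Star Rating system,low,medium,positive,high,high,medium,high,medium,1728,12
Restricting television advertising of unhealthy foods,low,medium,positive,high,medium,low,high,high,,3
Reformulation to reduce sugar in sugar-sweetened beverages,low,medium,positive,medium,high,medium,high,medium,,10
Menu kilojoule labelling on fast food,low,medium,neutral,high,high,medium,high,high,,6
Supermarket shelf tags on healthier products,low,medium,neutral,high,high,medium,high,medium,,5
Workplace intervention to reduce sedentary behaviour,low,medium,neutral,high,high,medium,medium,low,28703,16
Sugar-sweetened beverages tax - 20%,low,medium,neutral,medium,medium,low,high,high,,2
Alcohol price increase: uniform volumetric tax,low,medium,negative,low,medium,low,high,high,,1
Package size cap on sugar-sweetened beverages,low,low,positive,low,low,low,low,medium,,4
National mass media campaign related to sugar-sweetened beverages,low,low,neutral,medium,medium,medium,high,medium,,11
Fuel excise: 10c per litre increase,low,low,negative,low,low,medium,high,high,7684,14
Restrictions on price promotions of sugar-sweetened beverages,low,low,negative,low,low,low,low,high,,9
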