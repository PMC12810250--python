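# Printed summary values of the published 27-species compilation of ocean-acidification
# calcification experiments on positive responders (surface-dwelling marine calcifiers).
# Columns: functional group; species; calcification rate unit; best-fit response type
# (linear|threshold); habitat region used for the regional etamax (coastal|polar);
# current and preindustrial TA-DIC (umol/kg); calcification rates at those conditions
# in rate_unit with 90% prediction-interval half-widths; percent calcification decline
# since preindustrial; NaOH dose (umol/kg TA) restoring preindustrial TA-DIC without and
# with air-sea equilibration (CDR efficiency 0.8, etamax 0.832 coastal / 0.904 polar);
# percent calcification-rate gain for +50 umol/kg NaOH without and with equilibration.
group,species,rate_unit,response,region,tadic_current,rate_current,rate_current_pi90,tadic_preindustrial,rate_preindustrial,rate_preindustrial_pi90,decline_pct,naoh_uneq,naoh_eq,resp_uneq_pct,resp_eq_pct
Algae,Halimeda opuntia,mmol/m2/h,linear,coastal,292,8.32e-02,4.16e-02,384,9.88e-02,4.44e-02,15.82,91,273,10.28,3.44
Algae,Hydrolithon reinboldii,mmol/g/h,linear,coastal,243,2.79e-03,4.40e-03,300,3.22e-03,4.40e-03,13.31,57,172,13.39,4.48
Algae,Lithophyllum sp.,mmol/g/h,threshold,coastal,293,2.34e-01,1.87e-01,386,2.41e-01,1.88e-01,2.68,93,278,1.87,0.76
Algae,Porolithon onkodes,mmol/m2/h,linear,coastal,333,2.16e+00,1.34e+00,437,2.33e+00,1.35e+00,7.42,104,312,3.85,1.29
Algae,Sporolithon durum,mmol/m2/h,linear,coastal,259,1.48e-01,3.00e-01,340,2.21e-01,3.05e-01,33.19,81,244,30.48,10.19
Coral,Acropora yongei,mmol/m2/h,linear,coastal,259,4.92e+00,3.32e+00,340,6.08e+00,3.36e+00,19.02,81,244,14.41,4.82
Coral,Duncanopsammia axifuga,mmol/m2/h,linear,coastal,486,2.39e+01,9.27e+00,765,3.11e+01,1.04e+01,22.90,279,835,5.32,1.78
Coral,Montastraea cavernosa,mmol/m2/h,linear,coastal,486,2.17e+00,8.67e-01,765,2.48e+00,9.12e-01,12.46,279,835,2.55,0.85
Coral,Pavona cactus,mmol/m2/h,linear,coastal,328,3.64e+00,1.59e+00,428,3.99e+00,1.61e+00,8.86,100,299,4.86,1.63
Coral,Plesiastrea versipora,mmol/m2/h,linear,coastal,270,2.32e+00,1.05e+00,357,2.55e+00,1.07e+00,9.02,87,259,5.72,1.91
Coral,Pocillopora verrucosa,mmol/m2/h,linear,coastal,321,2.49e+00,1.43e+00,417,2.79e+00,1.47e+00,10.99,96,287,6.44,2.15
Coral,Porites rus,mmol/m2/h,linear,coastal,328,6.31e+00,3.47e+00,428,6.94e+00,3.51e+00,9.04,100,298,4.98,1.67
Coral,Siderastrea radians,mmol/m2/h,linear,coastal,390,5.08e+00,4.72e+00,529,7.40e+00,4.89e+00,31.45,138,413,16.60,5.55
Coral,Solenastrea hyades,mmol/m2/h,threshold,coastal,395,2.81e+00,3.52e+00,537,2.83e+00,3.64e+00,0.97,141,423,0.62,0.27
Echinoderm,Eucidaris tribuloides,mmol/g/h,threshold,coastal,181,5.68e-04,7.33e-04,244,6.09e-04,7.70e-04,6.75,63,188,6.28,2.68
Foraminifera,Marginopora vertebralis,mmol/g/h,threshold,coastal,405,1.90e-03,6.94e-04,561,1.90e-03,7.23e-04,0.00,156,466,0.00,0.00
Gastropod,Concholepas concholepas,mmol/g/h,threshold,coastal,107,3.37e-03,1.57e-03,141,3.38e-03,1.59e-03,0.43,34,103,0.49,0.29
Gastropod,Littorina littorea,mmol/g/h,linear,coastal,202,2.20e-04,3.06e-04,278,3.32e-04,3.15e-04,33.53,76,229,33.00,11.04
Gastropod,Strombus alatus,mmol/g/h,linear,coastal,202,1.49e-04,1.76e-04,278,2.67e-04,1.86e-04,44.37,76,229,52.17,17.45
Gastropod,Urosalpinx cinerea,mmol/g/h,linear,coastal,202,1.50e-04,1.58e-04,278,2.42e-04,1.64e-04,38.16,76,229,40.37,13.50
Mollusk,Argopecten irradians,mmol/g/h,linear,coastal,235,4.93e-04,3.32e-04,334,6.24e-04,3.62e-04,21.09,99,296,13.51,4.52
Mollusk,Crassostrea gigas,mmol/g/h,linear,coastal,246,3.03e-04,7.38e-05,324,3.61e-04,8.29e-05,16.14,78,233,12.34,4.13
Mollusk,Crassostrea virginica,mmol/g/h,threshold,coastal,98,2.22e-04,5.08e-04,120,2.29e-04,5.10e-04,3.22,22,67,6.30,2.58
Mollusk,Mercenaria mercenaria,mmol/g/h,threshold,coastal,235,6.38e-05,5.50e-05,334,7.01e-05,5.88e-05,8.96,99,296,6.39,2.58
Mollusk,Mya arenaria,mmol/g/h,linear,coastal,235,1.03e-03,7.28e-04,334,1.74e-03,8.23e-04,40.70,99,296,34.71,11.61
Mollusk,Mytilus edulis,mmol/g/h,linear,coastal,243,3.08e-04,2.96e-04,335,3.64e-04,3.03e-04,15.62,92,275,10.08,3.37
Pteropod,Limacina helicina,mmol/g/h,linear,polar,165,5.44e-04,1.81e-04,268,8.73e-04,2.18e-04,37.70,103,373,29.31,8.12
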