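conc.bulk.NH4.a = 145.80869450650852
conc.bulk.NH4.b = -0.35
conc.bulk.NO3.a = 42.49152065201698
conc.bulk.NO3.b = -0.25
conc.bulk.SO4.a = 363.75650005628796
conc.bulk.SO4.b = -0.4
conc.throughfall.NH4.a = 195.38365063872143
conc.throughfall.NH4.b = -0.35
conc.throughfall.NO3.a = 66.28677221714649
conc.throughfall.NO3.b = -0.25
conc.throughfall.SO4.a = 662.0368301024441
conc.throughfall.SO4.b = -0.4
enrichment.NH4 = 1.34
enrichment.NO3 = 1.56
enrichment.SO4 = 1.82
gm_precip_mm = 1675.011991990388
ph.bulk.c = 4.540460551717578
ph.bulk.d = 0.3
ph.throughfall.c = 4.840460551717578
ph.throughfall.d = 0.3
seed = 1234
sigma_log = 0.3
sigma_ph = 0.25
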