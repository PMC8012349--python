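compound,class,vip_sweetness_2011_2012,vip_sweetness_2013_2015,vip_sweetness_2016_2017,p_adj_sweetness,vip_liking_2011_2012,vip_liking_2013_2015,vip_liking_2016_2017,p_adj_liking
Glucose,sugar,1.68,2.14,1.52,,1.19,2.18,1.65,
Fructose,sugar,1.60,1.62,1.79,,1.00,1.65,1.80,
Sucrose,sugar,2.17,2.10,0.27,,2.19,2.32,0.20,
1-Penten-3-one,ketone,1.76,1.26,1.34,0.0000,1.87,1.31,1.23,0.0000
"2-Pentenal, (E)-",aldehyde,1.52,1.53,1.76,0.0000,1.83,1.48,1.71,0.0000
"2-Penten-1-ol, (Z)-",alcohol,0.19,1.12,2.00,1.0000,0.33,1.02,1.94,1.0000
Heptanal,aldehyde,1.36,1.26,1.60,0.0000,1.43,1.13,1.38,0.0000
"5-Hepten-2-one, 6-methyl-",ketone,1.16,1.42,0.49,0.0000,1.31,1.20,0.41,0.0000
"Butanoic acid, butyl ester",ester,1.38,1.48,0.88,0.0013,1.17,1.48,1.03,0.3781
"Acetic acid, hexyl ester",ester,1.39,1.24,0.39,0.0013,1.17,1.12,0.52,1.0000
"Butanoic acid, 3-methyl-, butyl ester",ester,1.23,1.33,0.77,0.0000,1.05,1.42,1.02,0.0033
"Butanoic acid, pentyl ester",ester,1.28,1.18,0.00,0.0000,1.28,1.12,,0.0000
Nonanal,aldehyde,1.16,0.81,1.36,0.0000,1.33,0.77,1.30,0.0013
"Butanoic acid, hexyl ester",ester,1.50,0.90,1.71,0.0467,1.27,0.87,1.70,1.0000
"Butanoic acid, octyl ester",ester,1.01,1.30,1.30,0.0007,0.79,1.32,1.40,0.2430
"Butanoic acid, decyl ester",ester,1.06,1.03,1.23,0.0000,1.01,1.07,1.27,0.0005
gamma-Dodecalactone,lactone,1.51,1.25,0.74,0.0000,1.54,1.21,0.84,0.0000
"Hexanoic acid, butyl ester",ester,1.34,1.44,,0.0002,1.26,1.48,,1.0000
gamma-Decalactone,lactone,1.08,1.12,0.69,0.2637,,,,
"Acetic acid, butyl ester",ester,1.16,1.34,0.44,0.0371,,,,
"2-Hexenal, (E)-",aldehyde,1.17,0.52,1.61,0.0000,,,,
Benzaldehyde,aldehyde,1.01,1.99,,1.0000,,,,
"Butanoic acid, phenylmethyl ester",ester,1.03,1.04,,1.0000,,,,
"Butanoic acid, propyl ester",ester,,,,,1.18,1.09,0.86,1.0000
Methyl Isobutyl Ketone,ketone,,,,,0.79,1.07,1.47,1.0000
"Butanoic acid, 3-methyl-, octyl ester",ester,,,,,0.91,1.21,1.05,1.0000
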