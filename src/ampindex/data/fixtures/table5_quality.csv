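region,effectiveness,safety,responsiveness,quality
Lombardia,110.39,106.13,116.90,110.87
Veneto,114.31,110.61,103.35,109.14
Trento,94.13,108.13,135.07,108.59
Toscana,111.74,102.10,104.52,105.88
Piemonte,98.17,103.49,111.83,104.19
Abruzzo,94.05,103.65,111.36,102.29
Umbria,98.13,97.90,109.05,101.30
Emilia-Romagna,112.35,81.11,120.65,100.55
Friuli-Venezia Giulia,92.42,98.30,110.66,99.60
Valle d'Aosta,82.62,103.38,120.53,98.65
Liguria,102.14,96.78,96.11,98.23
Bolzano,89.73,92.25,121.55,98.09
Marche,86.18,102.13,102.39,96.01
Basilicata,92.84,101.49,90.07,94.42
Lazio,99.56,92.12,81.75,90.26
Sicilia,100.46,92.01,76.92,88.21
Sardegna,78.21,92.05,95.50,87.64
Puglia,104.59,96.23,70.55,86.98
Calabria,97.99,83.00,75.56,83.99
Molise,101.55,79.26,70.74,80.83
Campania,94.51,79.50,71.65,80.24
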