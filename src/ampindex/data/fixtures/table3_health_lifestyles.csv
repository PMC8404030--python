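region,health_status,lifestyles
Abruzzo,97.41,93.56
Basilicata,82.76,95.74
Bolzano,127.73,111.77
Calabria,84.65,84.63
Campania,86.58,80.87
Emilia-Romagna,103.60,100.56
Friuli-Venezia Giulia,107.03,108.32
Lazio,100.41,93.14
Liguria,102.84,91.97
Lombardia,108.65,104.46
Marche,97.51,107.25
Molise,89.46,83.31
Piemonte,100.90,103.24
Puglia,94.82,89.69
Sardegna,94.83,96.31
Sicilia,87.62,89.01
Toscana,104.96,103.12
Trento,118.97,115.56
Umbria,90.64,96.67
Valle d'Aosta,92.00,104.89
Veneto,106.37,111.50
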