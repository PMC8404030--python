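region,cost_expenditure
Molise,119.20
Sardegna,117.72
Lazio,111.48
Puglia,106.84
Campania,105.93
Sicilia,103.66
Abruzzo,101.58
Calabria,99.98
Liguria,99.60
Basilicata,98.93
Bolzano,98.47
Umbria,98.09
Marche,95.19
Lombardia,93.30
Trento,92.58
Piemonte,89.84
Toscana,88.71
Friuli-Venezia Giulia,88.05
Valle d'Aosta,86.66
Veneto,82.23
Emilia-Romagna,81.87
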