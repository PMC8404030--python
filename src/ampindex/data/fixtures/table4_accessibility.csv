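region,accessibility
Valle d'Aosta,117.48
Trento,111.42
Bolzano,110.28
Friuli-Venezia Giulia,109.91
Umbria,107.25
Liguria,106.52
Marche,105.17
Toscana,102.84
Emilia-Romagna,102.84
Veneto,101.77
Molise,99.61
Piemonte,97.73
Lazio,97.29
Sardegna,94.97
Basilicata,93.45
Abruzzo,92.97
Puglia,91.12
Lombardia,86.99
Sicilia,85.44
Campania,77.48
Calabria,75.90
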