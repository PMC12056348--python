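name,lat,lon,elevation,occurrence
Bilpa,45.513,14.962,238,syntopy
Sv. Štefan,45.480,14.886,307,allotopy_muralis
Iški vintgar,45.907,14.494,378,syntopy
Planinska jama,45.822,14.247,477,allotopy_horvathi
Kočevska Reka,45.582,14.791,578,allotopy_muralis
Unška koliševka,45.816,14.265,578,syntopy
Ribnica,45.753,14.770,733,allotopy_muralis
Kuželjska stena,45.484,14.823,769,syntopy
Kovk,45.915,13.928,830,allotopy_muralis
Fridrihštajn,45.611,14.860,946,allotopy_muralis
Velike bele stene,45.675,14.708,1007,allotopy_horvathi
Kameni zid,45.613,14.735,1052,syntopy
Trnovski gozd,45.957,13.895,1097,allotopy_horvathi
Snežnik,45.599,14.397,1259,allotopy_horvathi
Orlovica,45.523,14.436,1279,allotopy_horvathi
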