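species,length_min,length_max,width_min,width_max,diameter_min,diameter_max
Brigantedinium simplex,,,,,29,54
Islandinium minutum,,,,,29,45
Islandinium? cezare,,,,,29,45
Pentapharsodinium dalei,,,,,19,36
Spiniferites elongatus,40,59,26,42,,
Spiniferites ramosus,30,46,17,43,,
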