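species,family,k,se,unit,m,l_min,l_max,range_source,ecology,corr_sign,d0
Chrysomya albiceps,Calliphoridae,143.52,5.61,ADD,7,5,12,ref31,necrophagous,negative,
Lucilia sericata,Calliphoridae,6023.2,297.2,ADH,7,5,12,ref31,necrophagous,negative,
Phormia regina,Calliphoridae,281,3.6,ADD,5,6,10,ref31,necrophagous,negative,
Fannia canicularis,Fanniidae,481.73,9.89,ADD,8,3.5,7,ref32,necrophagous,negative,
Necrobia rufipes,Cleridae,591,39.53,ADD,6,3.5,7,ref36,predatory,negative,
Omosita colon,Nitidulidae,514.1,8.7,ADD,6,2,3.6,ref38,necrophagous,negative,
Necrodes littoralis,Silphidae,469.89,24.59,ADD,8,15,25,ref39,necrophagous,negative,8.5
Thanatophilus sinuatus,Silphidae,360.46,10.75,ADD,7,9,12,ref39,necrophagous,negative,
Thanatophilus rugosus,Silphidae,362.758,4.97,ADD,6,8,12,ref39,necrophagous,negative,
Creophilus maxillosus,Staphylinidae,405.156,14.63,ADD,8,15,25,ref41,predatory,negative,11.7
Nasonia vitripennis,Pteromalidae,4768.8,431.5,ADH,6,1.3,2.2,ref43,parasitoid,positive,
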