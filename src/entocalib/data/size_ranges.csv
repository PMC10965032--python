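species,l_min,l_max,source
Chrysomya albiceps,5,12,ref31
Chrysomya albiceps,6,9,wikipedia
Lucilia sericata,5,12,ref31
Lucilia sericata,10,14,wikipedia
Phormia regina,6,10,ref31
Fannia canicularis,3.5,7,ref32
Fannia canicularis,4.5,7,ref33
Fannia canicularis,3.5,6,wikipedia
Necrobia rufipes,3.5,4.5,ref34
Necrobia rufipes,4,5.5,ref35
Necrobia rufipes,3.5,7,ref36
Necrobia rufipes,3.5,7,wikipedia
Omosita colon,2,3.6,ref37
Omosita colon,2,3.6,ref38
Omosita colon,2,3.5,wikipedia
Necrodes littoralis,15,25,ref39
Necrodes littoralis,16,25,ref40
Necrodes littoralis,12,22,ref15
Necrodes littoralis,15,25,wikipedia
Thanatophilus sinuatus,9,12,ref39
Thanatophilus sinuatus,9,12,ref40
Thanatophilus sinuatus,9,12,wikipedia
Thanatophilus rugosus,8,12,ref39
Thanatophilus rugosus,10,13,ref40
Thanatophilus rugosus,10,14,wikipedia
Creophilus maxillosus,15,25,ref41
Creophilus maxillosus,15,23,ref42
Creophilus maxillosus,15,24,ref14
Creophilus maxillosus,12,18,wikipedia
Nasonia vitripennis,1.3,2.2,ref43
Nasonia vitripennis,2,3,wikipedia
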