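[
 {
  "species": "Chrysomya albiceps",
  "family": "Calliphoridae",
  "k": 143.52,
  "se": 5.61,
  "unit": "ADD",
  "m": 7,
  "l_min": 5.0,
  "l_max": 12.0,
  "range_source": "ref31",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Lucilia sericata",
  "family": "Calliphoridae",
  "k": 6023.2,
  "se": 297.2,
  "unit": "ADH",
  "m": 7,
  "l_min": 5.0,
  "l_max": 12.0,
  "range_source": "ref31",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Phormia regina",
  "family": "Calliphoridae",
  "k": 281.0,
  "se": 3.6,
  "unit": "ADD",
  "m": 5,
  "l_min": 6.0,
  "l_max": 10.0,
  "range_source": "ref31",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Fannia canicularis",
  "family": "Fanniidae",
  "k": 481.73,
  "se": 9.89,
  "unit": "ADD",
  "m": 8,
  "l_min": 3.5,
  "l_max": 7.0,
  "range_source": "ref32",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Necrobia rufipes",
  "family": "Cleridae",
  "k": 591.0,
  "se": 39.53,
  "unit": "ADD",
  "m": 6,
  "l_min": 3.5,
  "l_max": 7.0,
  "range_source": "ref36",
  "ecology": "predatory",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Omosita colon",
  "family": "Nitidulidae",
  "k": 514.1,
  "se": 8.7,
  "unit": "ADD",
  "m": 6,
  "l_min": 2.0,
  "l_max": 3.6,
  "range_source": "ref38",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Necrodes littoralis",
  "family": "Silphidae",
  "k": 469.89,
  "se": 24.59,
  "unit": "ADD",
  "m": 8,
  "l_min": 15.0,
  "l_max": 25.0,
  "range_source": "ref39",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": 8.5
 },
 {
  "species": "Thanatophilus sinuatus",
  "family": "Silphidae",
  "k": 360.46,
  "se": 10.75,
  "unit": "ADD",
  "m": 7,
  "l_min": 9.0,
  "l_max": 12.0,
  "range_source": "ref39",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Thanatophilus rugosus",
  "family": "Silphidae",
  "k": 362.758,
  "se": 4.97,
  "unit": "ADD",
  "m": 6,
  "l_min": 8.0,
  "l_max": 12.0,
  "range_source": "ref39",
  "ecology": "necrophagous",
  "corr_sign": "negative",
  "d0": null
 },
 {
  "species": "Creophilus maxillosus",
  "family": "Staphylinidae",
  "k": 405.156,
  "se": 14.63,
  "unit": "ADD",
  "m": 8,
  "l_min": 15.0,
  "l_max": 25.0,
  "range_source": "ref41",
  "ecology": "predatory",
  "corr_sign": "negative",
  "d0": 11.7
 },
 {
  "species": "Nasonia vitripennis",
  "family": "Pteromalidae",
  "k": 4768.8,
  "se": 431.5,
  "unit": "ADH",
  "m": 6,
  "l_min": 1.3,
  "l_max": 2.2,
  "range_source": "ref43",
  "ecology": "parasitoid",
  "corr_sign": "positive",
  "d0": null
 }
]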