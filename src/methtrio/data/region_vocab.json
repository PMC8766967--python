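{
  "Island": "island",
  "island": "island",
  "N_Shore": "shore",
  "S_Shore": "shore",
  "Shore": "shore",
  "shore": "shore",
  "N_Shelf": "shelf",
  "S_Shelf": "shelf",
  "Shelf": "shelf",
  "shelf": "shelf",
  "OpenSea": "open_sea",
  "open_sea": "open_sea",
  "": "open_sea"
}
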