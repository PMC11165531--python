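{
  "description": "Optimized tissue-mimicking-material recipes; all values are weight ratios (percent). Stored as data only; no recipe-to-property model is attempted.",
  "recipes": {
    "muscle": {
      "di_water": 83.7,
      "gelatin": 15.07,
      "psyllium": 0.59,
      "formalin": 0.64
    },
    "soft_tissue": {
      "evaporated_milk": 99.6,
      "diazolidinyl_urea": 0.40
    },
    "adipose": {
      "di_water": 91.25,
      "gelatin": 6.93,
      "agar": 0.91,
      "diazolidinyl_urea": 0.27,
      "psyllium": 0.64
    },
    "skin": {
      "urethane_rubber_two_part": 100.0
    }
  }
}
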