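{
  "intercept": 326.7385,
  "terms": [
    {"knot": 1, "direction": "above", "coefficient": 130.654},
    {"knot": 3, "direction": "below", "coefficient": -93.33294},
    {"knot": 3, "direction": "above", "coefficient": 292.7998},
    {"knot": 4, "direction": "above", "coefficient": 151.775}
  ],
  "gcv": null
}
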