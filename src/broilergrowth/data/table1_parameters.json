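{
  "logistic": {"family": "logistic", "A": 3136.722, "b": 37.106, "k": 0.736},
  "gompertz": {"family": "gompertz", "A": 6854.354, "b": 4.882, "k": 0.241},
  "weibull": {"family": "weibull", "A": 13500.860, "b": 13436.664, "k": 0.005, "lam": 1.941},
  "hossfeld": {"family": "hossfeld", "A": 8872.315, "b1": 106.170, "b2": 1.963},
  "von_bertalanffy": {"family": "von_bertalanffy", "A": 20692.727, "b": 0.885, "k": 0.086}
}
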