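{
  "comment": "Published grey-relation degree and rank tables from the China healthcare-satisfaction study. Degrees are transcribed text-exact. Factor order matches the 'factors' list. 'regions' holds the per-region Deng-model rows for the pooled period.",
  "factors": [
    "health_exp_pct_gdp",
    "gov_pct_health_exp",
    "oop_pct",
    "beds_per_1000",
    "workforce_per_1000"
  ],
  "factor_labels": {
    "health_exp_pct_gdp": "Total health expenditure as a percentage of GDP",
    "gov_pct_health_exp": "Government's percentage of total expenditure on healthcare",
    "oop_pct": "Out-of-pocket percentage of individuals",
    "beds_per_1000": "Hospital beds per thousand population",
    "workforce_per_1000": "Healthcare workforce per thousand population"
  },
  "periods": {
    "pooled_2013_2015": {
      "deng": {"degrees": [0.7769, 0.82, 0.7853, 0.7837, 0.6865], "ranks": [4, 1, 2, 3, 5]},
      "absolute": {"degrees": [0.5904, 0.8321, 0.6664, 0.709, 0.696], "ranks": [5, 1, 4, 2, 3]},
      "relative": {"degrees": [0.9783, 0.9823, 0.9802, 0.9188, 0.8589], "ranks": [3, 1, 2, 4, 5]},
      "sdgra": {"degrees": [0.7844, 0.9072, 0.8233, 0.8139, 0.7775], "ranks": [4, 1, 2, 3, 5]},
      "ssgra": {"degrees": [0.68365, 0.82605, 0.72585, 0.74635, 0.69125], "ranks": [5, 1, 3, 2, 4]}
    },
    "y2013": {
      "deng": {"degrees": [0.745, 0.7794, 0.7727, 0.731, 0.6346], "ranks": [3, 1, 2, 4, 5]},
      "absolute": {"degrees": [0.6041, 0.8521, 0.8017, 0.6719, 0.6967], "ranks": [5, 1, 2, 4, 3]},
      "relative": {"degrees": [0.9877, 0.9822, 0.9975, 0.945, 0.866], "ranks": [2, 3, 1, 4, 5]},
      "sdgra": {"degrees": [0.7959, 0.9171, 0.8996, 0.8084, 0.7814], "ranks": [4, 1, 2, 3, 5]},
      "ssgra": {"degrees": [0.67455, 0.81575, 0.7872, 0.70145, 0.66565], "ranks": [4, 1, 2, 3, 5]}
    },
    "y2015": {
      "deng": {"degrees": [0.7904, 0.8394, 0.7836, 0.7642, 0.6833], "ranks": [2, 1, 3, 4, 5]},
      "absolute": {"degrees": [0.5717, 0.8005, 0.5683, 0.7083, 0.681], "ranks": [4, 1, 5, 2, 3]},
      "relative": {"degrees": [0.9622, 0.986, 0.9583, 0.9151, 0.8607], "ranks": [2, 1, 3, 4, 5]},
      "sdgra": {"degrees": [0.767, 0.8933, 0.7633, 0.8117, 0.7709], "ranks": [4, 1, 5, 2, 3]},
      "ssgra": {"degrees": [0.68105, 0.81995, 0.67595, 0.73625, 0.68215], "ranks": [4, 1, 5, 2, 3]}
    }
  },
  "regions": {
    "East China (without Shanghai)": {"degrees": [0.6391, 0.8485, 0.9392, 0.9796, 0.8953], "ranks": [5, 4, 2, 1, 3]},
    "Central China": {"degrees": [0.8977, 0.7401, 0.7276, 0.8655, 0.5995], "ranks": [1, 3, 4, 2, 5]},
    "West China (without Chongqing)": {"degrees": [0.7261, 0.5975, 0.9935, 0.8819, 0.6057], "ranks": [3, 5, 1, 2, 4]},
    "Northeast China": {"degrees": [0.8647, 0.8804, 0.5304, 0.7522, 0.8387], "ranks": [2, 1, 5, 4, 3]},
    "Beijing": {"degrees": [0.5517, 0.8814, 0.5722, 0.599, 0.3333], "ranks": [4, 1, 3, 2, 5]},
    "Shanghai": {"degrees": [0.8571, 0.6782, 0.5872, 0.6691, 0.4922], "ranks": [1, 2, 4, 3, 5]},
    "Tianjin": {"degrees": [0.5878, 0.8373, 0.8155, 0.7809, 0.9959], "ranks": [5, 2, 3, 4, 1]},
    "Chongqing": {"degrees": [0.8684, 0.9167, 0.9021, 0.5253, 0.4178], "ranks": [3, 1, 2, 4, 5]}
  }
}
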