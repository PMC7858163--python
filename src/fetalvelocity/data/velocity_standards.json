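{
  "name": "Fetal growth velocity increment standard",
  "ga_unit": "weeks",
  "value_unit": "mm/wk",
  "ga_range": [16.0, 38.0],
  "biometries": {
    "HC": {
      "mean": {"powers": [2.0, 2.0], "coefficients": [10.43136, 1.377907, -1.431528], "scale": 10.0},
      "sd": {"powers": [1.0], "coefficients": [0.1791373, 0.0425136], "scale": 1.0},
      "decimals": 2
    },
    "BPD": {
      "mean": {"powers": [2.0, 2.0], "coefficients": [2.263092, 0.6066072, -0.5224027], "scale": 10.0},
      "sd": {"powers": [1.0], "coefficients": [0.3886744, 0.0022155], "scale": 1.0},
      "decimals": 1
    },
    "OFD": {
      "mean": {"powers": [2.0, 2.0], "coefficients": [4.308462, 0.2489315, -0.3629665], "scale": 10.0},
      "sd": {"powers": [1.0], "coefficients": [-0.1167106, 0.0273527], "scale": 1.0},
      "decimals": 1
    },
    "AC": {
      "mean": {"powers": [-2.0, 3.0], "coefficients": [10.56711, 3.392895, -0.0285397], "scale": 10.0},
      "sd": {"powers": [3.0], "coefficients": [1.137471, 0.0349324], "scale": 10.0},
      "decimals": 1
    },
    "FL": {
      "mean": {"powers": [-1.0, 3.0], "coefficients": [1.474157, 2.899183, -0.0147426], "scale": 10.0},
      "sd": {"powers": [3.0], "coefficients": [0.2507282, 0.0035916], "scale": 10.0},
      "decimals": 1
    }
  }
}
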