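{
  "schema_version": 1,
  "regime": "persistent",
  "provenance": {
    "method": "search_regime_parameters",
    "target_regime": "persistent",
    "seed": 1,
    "budget": 10000,
    "found_index": 0,
    "bounds": {
      "k1": [
        0.55,
        0.7
      ],
      "k_minus1": [
        1.9,
        2.0
      ],
      "k2": [
        3.2,
        3.6
      ],
      "a0": [
        0.5,
        1.0
      ],
      "x0": [
        0.8,
        0.9
      ],
      "c0": [
        0.55,
        0.65
      ],
      "sigma": [
        0.02,
        0.06
      ],
      "gamma": [
        0.005,
        0.02
      ],
      "delta": [
        0.2,
        0.4
      ],
      "lambda_Y": [
        1.0,
        1.0
      ]
    },
    "note": "uniform random search over the bounds box; start state and grid chosen with the fixture"
  },
  "rates": {
    "k1": 0.6267732437050385,
    "k_minus1": 1.9950463696325935,
    "k2": 3.2576638450878534
  },
  "init": {
    "x0": 0.8311831452010486,
    "a0": 0.9743247235686219,
    "c0": 0.5923326448972576,
    "x_start": 0.8311831452010486,
    "y_start": 0.2
  },
  "noise": {
    "sigma": 0.05310810375281766,
    "lambda_Y": 1.0,
    "delta": 0.3099187375346119,
    "mark": {
      "type": "constant",
      "gamma": 0.01113798704553742
    }
  },
  "sim": {
    "dt": 0.001,
    "t_end": 20.0
  }
}
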