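{
  "schema_version": 1,
  "regime": "end_b",
  "provenance": {
    "method": "search_regime_parameters",
    "target_regime": "end_b",
    "seed": 1,
    "budget": 10000,
    "found_index": 0,
    "bounds": {
      "k1": [
        0.1,
        0.3
      ],
      "k_minus1": [
        0.9,
        1.1
      ],
      "k2": [
        1.2,
        1.4
      ],
      "a0": [
        1e-30,
        1e-28
      ],
      "x0": [
        0.9,
        1.0
      ],
      "c0": [
        0.6,
        0.7
      ],
      "sigma": [
        0.2,
        0.4
      ],
      "gamma": [
        0.02,
        0.06
      ],
      "delta": [
        0.3,
        0.6
      ],
      "lambda_Y": [
        1.0,
        1.0
      ]
    },
    "note": "uniform random search over the bounds box; start state and grid chosen with the fixture"
  },
  "rates": {
    "k1": 0.20236432494005135,
    "k_minus1": 1.0900927392651871,
    "k2": 1.2288319225439266
  },
  "init": {
    "x0": 0.9311831452010486,
    "a0": 9.491629526658714e-29,
    "c0": 0.6423326448972575,
    "x_start": 0.9311831452010486,
    "y_start": 0.2
  },
  "noise": {
    "sigma": 0.3655405187640884,
    "lambda_Y": 1.0,
    "delta": 0.46487810630191784,
    "mark": {
      "type": "constant",
      "gamma": 0.03636796545476645
    }
  },
  "sim": {
    "dt": 0.001,
    "t_end": 25.0
  }
}
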