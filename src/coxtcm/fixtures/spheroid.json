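{
  "name": "spheroid",
  "model": "coxian",
  "growth": {
    "variant": "logistic",
    "lambda0": 0.12,
    "umax": 0.0066
  },
  "mortality": {"eta": 0.0035},
  "tcm": {"n": 5, "k1": 0.1682, "p": 0.9},
  "concentrations": [0.0, 5.0, 10.0],
  "sample_times": [0.0, 1.0, 2.0, 3.0, 6.0, 24.0, 48.0, 72.0],
  "w0": 0.002,
  "time_unit": "hour",
  "solver": {"method": "LSODA", "rtol": 1e-08, "atol": 1e-12},
  "seed": 0
}
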