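{
  "name": "mouse150",
  "model": "coxian",
  "growth": {
    "variant": "simeoni",
    "lambda0": 0.25,
    "lambda1": 0.4603,
    "phi": 20
  },
  "mortality": {"eta": 0.7816},
  "tcm": {"n": 4, "k1": 0.2859, "p": 0.44268},
  "pk": {"k01": 1.6, "k21": 0.2353, "k12": 0.1699, "V": 1028},
  "schedule": {
    "events": [
      {"time": 13, "amount": 45000000.0},
      {"time": 14, "amount": 45000000.0},
      {"time": 15, "amount": 45000000.0},
      {"time": 16, "amount": 45000000.0},
      {"time": 17, "amount": 45000000.0},
      {"time": 18, "amount": 45000000.0},
      {"time": 19, "amount": 45000000.0},
      {"time": 20, "amount": 45000000.0},
      {"time": 21, "amount": 45000000.0},
      {"time": 22, "amount": 45000000.0}
    ],
    "horizon": 40
  },
  "w0": 0.0121,
  "time_unit": "day",
  "solver": {"method": "LSODA", "rtol": 1e-08, "atol": 1e-12},
  "seed": 0
}
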