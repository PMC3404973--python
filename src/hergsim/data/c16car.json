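{
  "condition": "C16CAR",
  "rates": {
    "k12": {"a": 0.02007341, "b": 0.07865593, "v0": 0.0},
    "k21": {"a": 0.2364064, "b": -0.00011822938, "v0": 0.0},
    "k23": {"a": 0.02927204, "b": 0.0, "v0": 0.0},
    "k32": {"a": 0.01686841, "b": 0.0, "v0": 0.0},
    "k34": {"a": 0.15066403, "b": 0.0231023, "v0": 0.0},
    "k43": {"a": 0.00037433, "b": -0.04078603, "v0": 0.0},
    "k45": {"a": 0.16042237, "b": 0.01554485, "v0": 4.5},
    "k54": {"a": 0.03731608, "b": -0.05090733, "v0": 4.5}
  }
}
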