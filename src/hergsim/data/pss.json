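{
  "condition": "PSS",
  "rates": {
    "k12": {"a": 0.01507341, "b": 0.001459408, "v0": 0.0},
    "k21": {"a": 0.05364064, "b": -0.19822938, "v0": 0.0},
    "k23": {"a": 0.08927204, "b": 0.0, "v0": 0.0},
    "k32": {"a": 15686841, "b": 0.0, "v0": 0.0},
    "k34": {"a": 0.01066403, "b": 0.00131023, "v0": 0.0},
    "k43": {"a": 0.0005743, "b": -0.0006156, "v0": 0.0},
    "k45": {"a": 0.05042237, "b": 0.00854485, "v0": 18.0},
    "k54": {"a": 0.01731608, "b": -0.04090733, "v0": 18.0}
  }
}
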