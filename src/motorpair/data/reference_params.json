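{
  "Kin1": {
    "direction": 1,
    "v0": 586,
    "step_size": 8,
    "k_forward0": 76,
    "k_backstep": 3,
    "k_detach0": 0.96,
    "f_stall": 6,
    "f_detach": 6.8,
    "k_reattach": 100,
    "stiffness": 0.2
  },
  "Kin2": {
    "direction": 1,
    "v0": 307,
    "step_size": 8,
    "k_forward0": 41,
    "k_backstep": 3,
    "k_detach0": 0.76,
    "f_stall": 6,
    "f_detach": 3,
    "k_reattach": 300,
    "stiffness": 0.2
  },
  "Kin3": {
    "direction": 1,
    "v0": 910,
    "step_size": 8,
    "k_forward0": 117,
    "k_backstep": 3,
    "k_detach0": 0.16,
    "f_stall": 6,
    "f_detach": 1.3,
    "k_reattach": 990,
    "stiffness": 0.2
  },
  "DDB": {
    "direction": -1,
    "v0": 360,
    "step_size": 8,
    "k_forward0": 60,
    "k_backstep": 5,
    "k_detach0": 0.1,
    "f_stall": 3.6,
    "f_detach": "ideal",
    "k_reattach": 5,
    "stiffness": 0.2
  }
}
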