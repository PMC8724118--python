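{
  "name": "calibrated",
  "k_a": [
    -0.006523,
    0.2758,
    -0.2631,
    0.2629,
    0.2739,
    0.01782,
    -0.07129,
    0.00382,
    0.005276
  ],
  "k_b": [
    6.753415123169772,
    -4.796948871285135,
    -15.563109949651821,
    14.146170078411616,
    19.857407608104612,
    -2.4919690464792725,
    1.1286839052732869,
    6.363764651646998,
    -8.161251114713002
  ],
  "p": 1.6,
  "Et_GPa": 15.0
}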