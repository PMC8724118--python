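{
  "name": "printed",
  "k_a": [-6.523e-3, 2.758e-1, -2.631e-1, 2.629e-1, 2.739e-1, 1.782e-2, -7.129e-2, 3.820e-3, 5.276e-3],
  "k_b": [6.238e-1, 1.157e1, -1.343e1, -1.159e1, 1.879e1, 1.206e-1, -8.538, -8.001, -1.051e1],
  "p": 1.6,
  "Et_GPa": 15.0
}
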