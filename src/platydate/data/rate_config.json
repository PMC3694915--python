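{
  "pergen": [9.70e-9, 1.36e-8],
  "node_generation_times": {
    "Crown Platyrrhini": 16.0,
    "Atelidae branching": 16.0,
    "Crown Cebidae": 15.0,
    "Crown Anthropoidea": 16.0,
    "Crown Catarrhini": 19.5,
    "Homo/Pan": 27.0
  }
}
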