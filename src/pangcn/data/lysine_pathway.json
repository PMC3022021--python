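{
  "name": "L-Aspartate to L-Lysine biosynthesis",
  "steps": [
    {"name": "lysC", "ec": ["2.7.2.4"]},
    {"name": "asd", "ec": ["1.2.1.11"]},
    {"name": "dapA", "ec": ["4.2.1.52"]},
    {"name": "dapB", "ec": ["1.3.1.26"]},
    {"name": "dapD", "ec": ["2.3.1.89", "2.3.1.117"]},
    {"name": "araT", "ec": ["2.6.1.57"]},
    {"name": "hipO3", "ec": ["3.5.1.47"]},
    {"name": "dapF", "ec": ["5.1.1.7"]},
    {"name": "lysA", "ec": ["4.1.1.20"]}
  ]
}
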