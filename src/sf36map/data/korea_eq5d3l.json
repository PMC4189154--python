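{
  "name": "korea",
  "description": "Korean EQ-5D-3L time trade-off value set (N3 model). Transcribed from the South Korean TTO valuation study (Lee YK et al., Value Health 2009; doi:10.1111/j.1524-4733.2009.00579.x). Anchors: 11111 -> 1.0, 33333 -> -0.171.",
  "constant": 0.050,
  "decrements": {
    "MO": [0.096, 0.418],
    "SC": [0.046, 0.136],
    "UA": [0.051, 0.208],
    "PD": [0.037, 0.151],
    "AD": [0.043, 0.158]
  },
  "n3": 0.050
}
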