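[
  {
    "name": "thoracic-straight-26",
    "comment": "Illustrative straight thoracic tube graft (dimensions are not vendor-certified).",
    "length": 116,
    "D_prox": 26,
    "D_dist": 26,
    "amplitude": 9,
    "wire": 0.4,
    "peaks": 8,
    "positions": [10, 42, 74, 106]
  },
  {
    "name": "thoracic-straight-30",
    "comment": "Illustrative straight thoracic tube graft, larger diameter.",
    "length": 120,
    "D_prox": 30,
    "D_dist": 30,
    "amplitude": 10,
    "wire": 0.5,
    "peaks": 8,
    "positions": [10, 40, 70, 100]
  },
  {
    "name": "thoracic-tapered-30-26",
    "comment": "Illustrative tapered thoracic tube graft.",
    "length": 120,
    "D_prox": 30,
    "D_dist": 26,
    "amplitude": 10,
    "wire": 0.5,
    "peaks": 8,
    "positions": [10, 40, 70, 100]
  }
]
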