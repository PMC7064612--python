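{
  "description": "Published donor groups defined by which CD43/CD49d/CD62L component subpopulations are present among sm14+16+ monocytes (adhesion-marker single-cell profiles a-e; profile e is unique to donor 10).",
  "profiles": {
    "a": [2, 4, 8, 14, 15, 16, 19, 21, 25],
    "b": [1, 3, 6, 12, 13],
    "c": [7, 9, 22, 23],
    "d": [17, 18, 20, 24],
    "e": [10]
  }
}
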