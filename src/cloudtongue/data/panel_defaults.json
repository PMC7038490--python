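{
  "_comment": "Default 40-member sensory-panel word-selection probabilities (%), aligned with lexicons.json order. jiang is fully published (votes 20/10/4/4/2); the other flavors are anchored by published values (feng n1=35, n5=5; nong n1=40; mild n1=n2=30) with the remaining splits being documented package assumptions.",
  "panel_size": 40,
  "frequencies_percent": {
    "jiang": [50, 25, 10, 10, 5],
    "feng":  [35, 25, 20, 15, 5],
    "nong":  [40, 25, 15, 10, 10],
    "mild":  [30, 30, 20, 10, 10]
  },
  "jiang_counts": [20, 10, 4, 4, 2]
}
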