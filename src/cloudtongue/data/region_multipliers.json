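{
  "_comment": "Published ellipse-boundary multipliers k1..k5 per flavor (semi-axis = k * En per PC); outermost is the 3*En cap.",
  "jiang": [1.05, 1.50, 1.76, 2.24, 3.00],
  "feng":  [0.83, 1.30, 1.76, 2.24, 3.00],
  "nong":  [0.90, 1.39, 1.95, 2.24, 3.00],
  "mild":  [0.75, 1.21, 1.50, 1.95, 3.00]
}
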