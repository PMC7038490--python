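{
  "_comment": "Five standardized taste-description words per flavor (GB/T 33405-2016), ordered centre -> periphery, i.e. by panel-vote frequency descending.",
  "jiang": ["Fully mellow", "Elegant and delicate", "Full bodied", "Long aftertaste", "Coordination"],
  "feng":  ["Sweet and cool", "Long clean tail", "Mellow and elegant", "All tastes harmonize", "Mellow fullness"],
  "nong":  ["Soft and sweet", "Sweet and refreshing", "Mellow", "Alcohol harmonious", "Long aftertaste"],
  "mild":  ["Pure fragrance", "Long aftertaste", "Sweet and soft", "Natural coordination", "Sweet and refreshing"]
}
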