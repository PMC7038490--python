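{
  "jiang": {"pc1": {"ex": 41.6501, "en": 2.7506, "he": 1.2743},
            "pc2": {"ex": -23.6840, "en": 2.3288, "he": 1.1007}},
  "feng":  {"pc1": {"ex": -31.8733, "en": 2.6604, "he": 0.3852},
            "pc2": {"ex": -23.6339, "en": 3.6078, "he": 1.8173}},
  "nong":  {"pc1": {"ex": 30.2356, "en": 2.9954, "he": 1.3505},
            "pc2": {"ex": -27.0657, "en": 2.3639, "he": 1.6552}},
  "mild":  {"pc1": {"ex": 4.4596, "en": 3.3641, "he": 0.5800},
            "pc2": {"ex": -36.4820, "en": 2.1433, "he": 0.7641}}
}
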