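{
  "ASTM D6751": {
    "kv": {"lower": 1.9, "upper": 6.0, "units": "mm^2/s"},
    "rho": {"lower": 0.85, "upper": 0.90, "units": "kg/L"},
    "cn": {"lower": 47, "units": ""},
    "fp": {"lower": 130, "units": "degC"},
    "os": {"lower": 3, "lower_strict": true, "units": "h"}
  },
  "EN 14214": {
    "kv": {"lower": 3.5, "upper": 5.5, "units": "mm^2/s"},
    "cn": {"lower": 51, "units": ""},
    "iv": {"upper": 120, "units": "g I2/100 g"},
    "fp": {"lower": 101, "units": "degC"},
    "os": {"lower": 6, "lower_strict": true, "units": "h"},
    "linolenic": {"upper": 12, "units": "wt %"},
    "pufa_ge4db": {"upper": 1, "units": "wt %"},
    "cfpp": {"upper": 5, "units": "degC"}
  },
  "EN 14213": {
    "hhv": {"lower": 35, "units": "MJ/kg"}
  }
}
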