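[
  {"polymorph_id": "Y",    "nu_cn_cm1": [2231.0], "color": "yellow", "habit": "block"},
  {"polymorph_id": "YN",   "nu_cn_cm1": [2222.0], "color": "yellow", "habit": "needle"},
  {"polymorph_id": "ON",   "nu_cn_cm1": [2224.0], "color": "orange", "habit": "needle"},
  {"polymorph_id": "OP",   "nu_cn_cm1": [2226.0], "color": "orange", "habit": "plate"},
  {"polymorph_id": "R",    "nu_cn_cm1": [2211.0], "color": "red",    "habit": "plate"},
  {"polymorph_id": "RPL",  "nu_cn_cm1": [2210.0, 2215.0], "color": "red", "habit": "plate", "tentative": true},
  {"polymorph_id": "Y04",  "nu_cn_cm1": [2222.0], "color": "yellow", "habit": "block"},
  {"polymorph_id": "YT04", "nu_cn_cm1": [2224.0], "color": "yellow", "habit": "prism"},
  {"polymorph_id": "Y19",  "nu_cn_cm1": [2224.0], "color": "yellow", "habit": "plate"}
]
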