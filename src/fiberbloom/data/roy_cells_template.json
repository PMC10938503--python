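{
  "_note": "Unit-cell reference template. The ON entry carries the 3D-ED-determined cell; every other entry is a SYNTHETIC placeholder (plausible but invented lattice parameters) meant to be replaced with curated database cells by the user. Placeholders are flagged with synthetic=true.",
  "entries": [
    {"polymorph_id": "ON", "refcode": "QAXMEH54", "a": 3.941, "b": 18.47, "c": 16.30, "alpha": 90.0, "beta": 92.8, "gamma": 90.0, "synthetic": false},
    {"polymorph_id": "Y",  "refcode": "SYNTH-Y",  "a": 8.50,  "b": 16.41, "c": 8.54,  "alpha": 90.0, "beta": 91.8, "gamma": 90.0, "synthetic": true},
    {"polymorph_id": "R",  "refcode": "SYNTH-R",  "a": 7.49,  "b": 7.79,  "c": 11.91, "alpha": 75.5, "beta": 77.8, "gamma": 63.6, "synthetic": true},
    {"polymorph_id": "OP", "refcode": "SYNTH-OP", "a": 7.98,  "b": 13.27, "c": 11.25, "alpha": 90.0, "beta": 104.7, "gamma": 90.0, "synthetic": true},
    {"polymorph_id": "YN", "refcode": "SYNTH-YN", "a": 4.59,  "b": 11.25, "c": 12.32, "alpha": 71.2, "beta": 89.9, "gamma": 88.1, "synthetic": true}
  ]
}
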