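{
  "comment": "ACMG/AMP 2015 criteria-combining rules. Each rule lists minimum counts per evidence tier (pvs=PVS1, ps=PS1-4, pm=PM1-6, pp=PP1-5, ba=BA1, bs=BS1-4, bp=BP1-7); a rule fires when every listed tier meets its minimum. Pathogenic and benign sides are evaluated independently; both firing is a conflict resolved to VUS.",
  "pathogenic": [
    {"pvs": 1, "ps": 1},
    {"pvs": 1, "pm": 2},
    {"pvs": 1, "pm": 1, "pp": 1},
    {"pvs": 1, "pp": 2},
    {"ps": 2},
    {"ps": 1, "pm": 3},
    {"ps": 1, "pm": 2, "pp": 2},
    {"ps": 1, "pm": 1, "pp": 4}
  ],
  "likely_pathogenic": [
    {"pvs": 1, "pm": 1},
    {"ps": 1, "pm": 1},
    {"ps": 1, "pp": 2},
    {"pm": 3},
    {"pm": 2, "pp": 2},
    {"pm": 1, "pp": 4}
  ],
  "benign": [
    {"ba": 1},
    {"bs": 2}
  ],
  "likely_benign": [
    {"bs": 1, "bp": 1},
    {"bp": 2}
  ]
}
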