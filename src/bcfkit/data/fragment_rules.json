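[
  {
    "rule_id": "A",
    "smarts_list": ["[Cl]"],
    "min_counts": [6],
    "conjunctive": false,
    "description": "Highly chlorinated compound: at least six chlorine atoms",
    "template": false
  },
  {
    "rule_id": "E",
    "smarts_list": ["O[a]", "[Cl,Br]a"],
    "min_counts": [1, 3],
    "conjunctive": true,
    "description": "Oxygen bound to an aromatic atom together with at least three halogens (Cl or Br) bound to an aromatic atom",
    "template": false
  },
  {
    "rule_id": "J",
    "smarts_list": ["[Si]"],
    "min_counts": [1],
    "conjunctive": false,
    "description": "Count-based template rule; default pattern flags silicon-containing compounds. Edit the SMARTS and min_counts to encode the intended fragment.",
    "template": true
  }
]
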