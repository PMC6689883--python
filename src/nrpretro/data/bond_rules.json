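[
  {
    "name": "AMINO",
    "tier": "primary",
    "smarts": "[CX3;$([CX3]=[OX1])]-[NX3]",
    "cut_pairs": [[0, 1]],
    "carbon": 0,
    "prioritized": true,
    "ring_exempt": false,
    "repair": {"carbon_side": "add_hydroxyl", "hetero_side": "none"}
  },
  {
    "name": "ESTER",
    "tier": "primary",
    "smarts": "[CX3;$([CX3]=[OX1])]-[OX2H0]",
    "cut_pairs": [[0, 1]],
    "carbon": 0,
    "prioritized": true,
    "ring_exempt": false,
    "repair": {"carbon_side": "add_hydroxyl", "hetero_side": "none"}
  },
  {
    "name": "THIOESTER",
    "tier": "primary",
    "smarts": "[CX3;$([CX3]=[OX1])]-[SX2H0]",
    "cut_pairs": [[0, 1]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": false,
    "repair": {"carbon_side": "add_hydroxyl", "hetero_side": "none"}
  },
  {
    "name": "HETEROCYCLE_THIAZOLE",
    "tier": "primary",
    "smarts": "[cX3]1[sX2][cX3][cX3][nX2]1",
    "cut_pairs": [[0, 4], [0, 1]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": true,
    "repair": {"carbon_side": "add_carboxyl", "hetero_side": "none"}
  },
  {
    "name": "HETEROCYCLE_THIAZOLE",
    "tier": "primary",
    "smarts": "[CX3]1=[NX2][CX4][CX4][SX2]1",
    "cut_pairs": [[0, 1], [0, 4]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": true,
    "repair": {"carbon_side": "add_carboxyl", "hetero_side": "none"}
  },
  {
    "name": "HETEROCYCLE_OXAZOLE",
    "tier": "primary",
    "smarts": "[cX3]1[oX2][cX3][cX3][nX2]1",
    "cut_pairs": [[0, 4], [0, 1]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": true,
    "repair": {"carbon_side": "add_carboxyl", "hetero_side": "none"}
  },
  {
    "name": "HETEROCYCLE_OXAZOLE",
    "tier": "primary",
    "smarts": "[CX3]1=[NX2][CX4][CX4][OX2]1",
    "cut_pairs": [[0, 1], [0, 4]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": true,
    "repair": {"carbon_side": "add_carboxyl", "hetero_side": "none"}
  },
  {
    "name": "CC",
    "tier": "secondary",
    "smarts": "[cX3]-!@[cX3]",
    "cut_pairs": [[0, 1]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": false,
    "repair": {"carbon_side": "none", "hetero_side": "none"}
  },
  {
    "name": "CC",
    "tier": "secondary",
    "smarts": "[CX4]-!@[CX4]",
    "cut_pairs": [[0, 1]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": false,
    "repair": {"carbon_side": "none", "hetero_side": "none"}
  },
  {
    "name": "ARYL_ETHER",
    "tier": "secondary",
    "smarts": "[cX3]-[OX2]-[#6]",
    "cut_pairs": [[0, 1]],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": false,
    "repair": {"carbon_side": "none", "hetero_side": "none"}
  },
  {
    "name": "GENERIC_CYCLE",
    "tier": "secondary",
    "smarts": null,
    "cut_pairs": [],
    "carbon": 0,
    "prioritized": false,
    "ring_exempt": true,
    "repair": {"carbon_side": "none", "hetero_side": "none"}
  }
]
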