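[
  {
    "name": "NMe",
    "site_smarts": "[NX3;H2][CX4][CX3](=[OX1])[OX2H1]",
    "attach_smiles": "C"
  },
  {
    "name": "NFo",
    "site_smarts": "[NX3;H2;!$([NX3][CX3]=[OX1])]",
    "attach_smiles": "C=O"
  }
]
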