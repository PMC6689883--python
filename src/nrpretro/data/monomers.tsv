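# Packaged monomer set: 20 proteinogenic amino acids + NRP-typical monomers.
# Format: code<TAB>smiles ; stereochemistry is parsed but ignored by matching.
Ala	N[C@@H](C)C(=O)O
Arg	N[C@@H](CCCNC(=N)N)C(=O)O
Asn	N[C@@H](CC(N)=O)C(=O)O
Asp	N[C@@H](CC(=O)O)C(=O)O
Cys	N[C@@H](CS)C(=O)O
Gln	N[C@@H](CCC(N)=O)C(=O)O
Glu	N[C@@H](CCC(=O)O)C(=O)O
Gly	NCC(=O)O
His	N[C@@H](Cc1c[nH]cn1)C(=O)O
Ile	N[C@@H](C(C)CC)C(=O)O
Leu	N[C@@H](CC(C)C)C(=O)O
Lys	N[C@@H](CCCCN)C(=O)O
Met	N[C@@H](CCSC)C(=O)O
Phe	N[C@@H](Cc1ccccc1)C(=O)O
Pro	OC(=O)[C@@H]1CCCN1
Ser	N[C@@H](CO)C(=O)O
Thr	N[C@@H](C(O)C)C(=O)O
Trp	N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O
Tyr	N[C@@H](Cc1ccc(O)cc1)C(=O)O
Val	N[C@@H](C(C)C)C(=O)O
Lac	CC(O)C(=O)O
Hiv	CC(C)C(O)C(=O)O
Orn	NCCC[C@@H](N)C(=O)O
Dab	NCC[C@@H](N)C(=O)O
Dha	NC(=C)C(=O)O
Dhb	NC(=CC)C(=O)O
bAla	NCCC(=O)O
Aib	CC(C)(N)C(=O)O
NMe-Gly	CNCC(=O)O
NMe-Ala	CN[C@@H](C)C(=O)O
NMe-Val	CN[C@@H](C(C)C)C(=O)O
NMe-Leu	CN[C@@H](CC(C)C)C(=O)O
NMe-Ile	CN[C@@H](C(C)CC)C(=O)O
Phg	NC(c1ccccc1)C(=O)O
Hpg	NC(c1ccc(O)cc1)C(=O)O
Sal	Oc1ccccc1C(=O)O
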