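# Drug-like ligand library for synthetic complexes (5-30 heavy atoms).
# code<TAB>smiles; the first block is rigid (no rotatable heavy-atom bonds).
L001	c1ccc2[nH]ccc2c1
L002	c1ccc2occc2c1
L003	c1ccc2ncccc2c1
L004	c1ccc2cnccc2c1
L005	c1ccc2[nH]cnc2c1
L006	O=c1ccc2ccccc2o1
L007	Cc1ccc2ccccc2n1
L008	Cn1cnc2c1c(=O)n(C)c(=O)n2C
L009	c1ncc2[nH]cnc2n1
L010	Cn1ccc2ccccc21
L011	CC(=O)Nc1ccc(O)cc1
L012	CC(=O)Oc1ccccc1C(=O)O
L013	CC(C)Cc1ccc(cc1)C(C)C(=O)O
L014	COc1ccc2cc(ccc2c1)C(C)C(=O)O
L015	CC(=O)NCCc1c[nH]c2ccc(OC)cc12
L016	NCCc1c[nH]c2ccc(O)cc12
L017	NCCc1ccc(O)c(O)c1
L018	CC(C)(C)NCC(O)c1ccc(O)c(CO)c1
L019	CN1CCC[C@H]1c1cccnc1
L020	CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O
L021	CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21
L022	CC(C(=O)O)c1cccc(c1)C(=O)c1ccccc1
L023	NCCc1c[nH]c2ccccc12
L024	CNCC(O)c1cccc(O)c1
L025	CCOC(=O)c1ccc(N)cc1
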