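# Core building-block library: 40 terminal precursor metabolites at which
# the backward search stops.  Amino acids, central carbon-metabolism acids,
# and the isoprenoid / polyketide / phenylpropanoid entry metabolites.
# One SMILES per line; trailing tab-separated name column.  Thioesters are
# stored unmasked; apply CoA masking consistently with your pipeline.
NCC(=O)O	glycine
C[C@H](N)C(=O)O	L-alanine
CC(C)[C@H](N)C(=O)O	L-valine
CC(C)C[C@H](N)C(=O)O	L-leucine
CC[C@H](C)[C@H](N)C(=O)O	L-isoleucine
O=C(O)[C@@H]1CCCN1	L-proline
N[C@@H](Cc1ccccc1)C(=O)O	L-phenylalanine
N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O	L-tryptophan
CSCC[C@H](N)C(=O)O	L-methionine
N[C@@H](CO)C(=O)O	L-serine
C[C@@H](O)[C@H](N)C(=O)O	L-threonine
N[C@@H](CS)C(=O)O	L-cysteine
N[C@@H](Cc1ccc(O)cc1)C(=O)O	L-tyrosine
NC(=O)C[C@H](N)C(=O)O	L-asparagine
NC(=O)CC[C@H](N)C(=O)O	L-glutamine
N[C@@H](CC(=O)O)C(=O)O	L-aspartate
N[C@@H](CCC(=O)O)C(=O)O	L-glutamate
NCCCC[C@H](N)C(=O)O	L-lysine
N=C(N)NCCC[C@H](N)C(=O)O	L-arginine
N[C@@H](Cc1c[nH]cn1)C(=O)O	L-histidine
CC(=O)C(=O)O	pyruvate
C=C(OP(=O)(O)O)C(=O)O	phosphoenolpyruvate
CC(=O)SCCNC(=O)CCNC(=O)[C@H](O)C(C)(C)COP(=O)(O)OP(=O)(O)OC[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1OP(=O)(O)O	acetyl-CoA
O=C(O)CC(=O)SCCNC(=O)CCNC(=O)[C@H](O)C(C)(C)COP(=O)(O)OP(=O)(O)OC[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1OP(=O)(O)O	malonyl-CoA
C[C@@](O)(CCO)CC(=O)O	mevalonate
C=C(C)CCOP(=O)(O)OP(=O)(O)O	isopentenyl diphosphate
CC(C)=CCOP(=O)(O)OP(=O)(O)O	dimethylallyl diphosphate
CC(C)=CCC/C(C)=C/CC/C(C)=C/COP(=O)(O)OP(=O)(O)O	farnesyl diphosphate
O=C(O)C1=C[C@@H](O)[C@@H](O)[C@H](O)C1	shikimate
C=C(OC1C=C(C(=O)O)C=CC1O)C(=O)O	chorismate
O=C(O)/C=C/c1ccccc1	cinnamate
O=C[C@H](O)[C@H](O)COP(=O)(O)O	erythrose 4-phosphate
OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O	D-glucose
O=C[C@H](O)COP(=O)(O)O	glyceraldehyde 3-phosphate
O=C(O)CCC(=O)C(=O)O	2-oxoglutarate
O=C(O)CC(=O)C(=O)O	oxaloacetate
O=C(O)CCC(=O)O	succinate
OC(CC(=O)O)(CC(=O)O)C(=O)O	citrate
CC(=O)O	acetate
O=C(O)CC(=O)O	malonate
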