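# Coenzyme A fragment rooted at the thiol sulfur (atom 0).
# Masking replaces this whole moiety, sulfur included, by a single "*"
# attachment point; unmasking splices it back at the same position with
# the natural stereochemistry shown here.
SCCNC(=O)CCNC(=O)[C@H](O)C(C)(C)COP(=O)(O)OP(=O)(O)OC[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1OP(=O)(O)O
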