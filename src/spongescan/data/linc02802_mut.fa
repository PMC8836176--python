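>LINC02802-MUT miR-486-5p site point-mutant (GUACAGG at 161-167 -> GUCCGGU)
GCGCAGGCGCCCAGAGGCGCACAGGAGACCUCAGGCCCAGACUCCACUCCCCAGCUGUGAAAGGACUGCU
GGCCAGACCCCCAAGCUAGCCCGCCAGGCCUCCAUAGAGCUGCCCAGCAUGGCUGCAUCCAGUACCAAGA
GUUGGUGGGAGACGGGUGAGGUCCGGUCUCAGUCUGCGGCCAAGACUCCGUCCUGCAAGACUCUUUGGCA
GUUGCACUGGGUACUGGCUGAGUUCUGGAAAACAGGAAUGUGAGCAGAGUGCUGCAGAUCUCCUUGUCAG
GAGCACCUAAGAACUGGCAUGACUCUACACCCUCUCUCCUUCUGCAAUGACCUCGUGUCAAGAUGGCAGA
CCCGCAGAGAUGAAUGUGCCUGGAUACCUGAGUCACCAGGUGGAGGAAACUCCCAUUGACAUGCAUCACA
CUCCACAUAUGAAACCCUUCUUUUUCUGCACUGUCACUGGGGUUAGGGAUUAUUACUCACUGCAACUUAG
CCUAGCAUUAAGUUGCUUGACUAAUACAAGUUUCAAUAAAUGUCGCUUCAUUUCCCAUG
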