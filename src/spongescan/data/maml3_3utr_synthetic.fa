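>MAML3-3UTR-SYNTHETIC synthetic stand-in for the MAML3 (NM_018717.5) 3'UTR: random background carrying one miR-486-5p 8mer site at 605-612 and one 7mer-m8 site at 1993-1999, all other seed-core matches masked
GAACAUGCCAUGGGUUAACCUUACACAUAAAAAUCACCCAGUGCAUCGGUAGACAAGUGGAAUCCUAAUU
UAAAAUGGGUUCUCUUCGUGGGCGAUUUAUUUAAGAGGCAUGCCUGGUUUUAUGUGCGAAUUCAAUUGCA
AGACUACCAAUUUCUGAAAUAAAAUUCCCGGAACAGACACUACAGCAUUGCGUACACAGUAGCUAUGUGG
CGUUGAAUAAUUCGUGUAGCAGAUGUCCCAGACCUAGAGGUAGCAAAACCGCGAAUGACUCCUCAAGGGU
CAGUGAUUUAUAUAUCCUCCUAAACUAGCACGAUGCGGCUUUUCUUGAUGAAAGGGUACUUUAACAGGUA
UGCGGGAGCUACGCAGGUGUGACAUGUGGAAGUCAUAUUAAUUUGUCCUAAUCCAAUCAUUGAGUGAAGA
GGUAUCGAUACUGCACAUACUCUCAAAGCACUCCCGGCGUCUGGAACAUCUCCGUCACCAAUUAAAACGA
UUUCCUCUAACCAUCGGCGUGGGGCAAUCUGACUGGUUCGCGAUCUAAAAACGCUUAUCACACAAUCCCU
AAAGUGGCUCGUUAUUGACACUCUGGCCCAAAUAGAGCUCGUUUGUACAGGAGUUUUCUUCAGACGUCCA
GGGCCUGAGGUCUUCCUUUGUACGGAAUGUUGAGCCCCUUGAUAUUUAAAUCUUUCUACGGCCGGGCGGA
AUGUUAAAAACUUUGUCCCCUGUAAUUUAGAACCGUUUAAGAGGUAGAAGGUAUAGUCGGUUUCUCGGGG
ACUUCCGUCGGACAUUACAUGGGUCAGCGUUACCCCUUGCUCACAUAGCUGUACCCUUACGCCAUUCGCC
UUUAGGCAAAACAAAAAUCCAAGAAUCCUCCUUCGAUACCAGAUUGUAACUAGCUAAUUAGUGUUGAUCU
UAUGUGCCUGGCGGCAGAUAAGGUACUUCCAUCGUGCAUUCCAUUAUUUUUGUUGAAGAAAGUGUUGUUC
UUGUACAGAGUAAAUUACAGUACAUCGUGAUUGAGCUUCGAUUCGUGUUUAAUUGCGACUAACUAAUACC
AGCUCCAUCUCAGCAUUGACCCUUUGAUCAGAAGCGUAUAUGCGGACACCUACGUGACACGUCACGGUAA
GAAAAGCUGUAAAGAUGAGGGUAAGGAUUUCAGACCGACAGUUUGUAAAAGCAAGGCUGGUGUCCCAUCG
UCACUAAUGUGCUAUACCCAUAUAUCCCAUGUACUCGAAGUCUCAAUAAACGUCGAUUCAAAUCGCACAC
ACUGCGGGCCGACAUGAGCUGAUUCGGGCACGAUCUAACACCGUCUUCCGACUGAGGUUAGUCAGAGCCC
AGUUAGGCCGUACUUGUUGUUCAACGUACUAAACGUGAGAUCGACAGAUGCUAGCCACCGCAAGCUAAGA
UCGGGCGAGUGUAAAAGCCGGUCGAAGCGCCCAUAGCUAGAGGGCGGUUUGCUGUUCGACUUCCUUAUCG
AUCAGAUCAUAACCAUAUGGCGUCGGGUAAGGGGCCCGGUGACCCUUCGCGCUUGUCUUGAACGCCCGAC
UGGCUAGUUUCUAAACGGUUUGACGAGGAAUCUUUCCUUCUCGGGUAUUGUCAGUUUCGACAUGGAUGCU
CAUCCCAUAUGUGAGCUGACUAUGGAUCAAUGCAAUAAGACAUCCGCUUUAGUUCGCGACGGCUUGACUA
AAUCUACCUACUAGUCUCAUAUCGUCUUCUUAGCAUCUAAGAAAUAGCUCUUACUCUCUGCUAGCGAUCU
GAAUACACGCAAUUUGGGUUGGUCUUUUGGCGCGACAAAGCCUUAUGGUCUAGAAUAGCUAAAAGCAAGA
UAUGGUCUCACUCGGGAAUGUUUCGCUUUGCUGCCAUUGUGAUUACCUAGCAUUCCAAUAUCUAGGCAUU
GUAUGAGGUUUAGGAUUUGAGCUGAAAUUUCUGGCGACGAUAAUAGUGCGCUGGGUAACUCUGGCAGAUG
GUGACGUUCAUUAGCUAAAAAAUAUCUACAUAGUACAGGUGUAAUAAUCGCCCAAGAAUAUCCUGGGUAG
GCUAUCUAUGCAACUGUGCCGCGGCGCCGAAAAAAAACUUAAGUUUUCACGCUACGUAGUCAACGCGUAG
GACAAUGUUUUUAAUCUACCGAUCACGUGGGUUUACCUGUGUUAUCUACACACUCCGUUAAUGUUGCCUG
CACCAUCAGUGCGUUUAACCGUUGGGUUUC
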