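# 5-(diethylamino)-2-formylphenyl naphthalene-2-sulfonate thiosemicarbazones 5a-5u
# transcribed from the published IUPAC names; formulas verified against printed HRMS data
CCN(CC)c1ccc(/C=N/NC(=S)Nc2cccc(Cl)c2Cl)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5a
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccc(Br)cc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5b
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccccc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5c
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccc(OC)cc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5d
CCN(CC)c1ccc(/C=N/NC(=S)Nc2cccc(Cl)c2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5e
CCN(CC)c1ccc(/C=N/NC(=S)NCC(C)C)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5f
CCN(CC)c1ccc(/C=N/NC(=S)NCCCSC)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5g
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccccc2C(F)(F)F)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5h
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccc(Cl)cc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5i
CCN(CC)c1ccc(/C=N/NC(=S)Nc2c(C)cccc2C)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5j
CCN(CC)c1ccc(/C=N/NC(=S)Nc2cccc(OC)c2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5k
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccc(F)cc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5l
CCN(CC)c1ccc(/C=N/NC(=S)NC)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5m
CCN(CC)c1ccc(/C=N/NC(=S)N)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5n
CCN(CC)c1ccc(/C=N/NC(=S)Nc2cccc([N+](=O)[O-])c2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5o
CCN(CC)c1ccc(/C=N/NC(=S)NC2CCCCC2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5p
CCN(CC)c1ccc(/C=N/NC(=S)NCc2ccc(Cl)cc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5q
CCN(CC)c1ccc(/C=N/NC(=S)Nc2ccccc2C)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5r
CCN(CC)c1ccc(/C=N/NC(=S)NCc2ccccc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5s
CCN(CC)c1ccc(/C=N/NC(=S)NCCc2ccccc2)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5t
CCN(CC)c1ccc(/C=N/NC(=S)Nc2c(Cl)cccc2Cl)c(OS(=O)(=O)c2ccc3ccccc3c2)c1 5u
# reference inhibitors
CN1CC[C@]23C=C[C@@H](O)C[C@@H]2Oc2c(OC)ccc(C1)c23 galantamine
C#CCN(C)CCCOc1ccc(Cl)cc1Cl clorgyline
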