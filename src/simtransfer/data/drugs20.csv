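query_name,generic_name,smiles,therapeutic_class,otc_flag
Loxonin,Loxoprofen,CC(C(=O)O)c1ccc(CC2CCCC2=O)cc1,analgesic,True
Voltaren,Diclofenac,OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl,analgesic,True
Myslee,Zolpidem,Cc1ccc(-c2nc3ccc(C)cn3c2CC(=O)N(C)C)cc1,hypnotic_anxiolytic,False
Flunitrazepam,Flunitrazepam,CN1c2ccc(cc2C(=NCC1=O)c1ccccc1F)[N+](=O)[O-],hypnotic_anxiolytic,False
Lexotan,Bromazepam,O=C1CN=C(c2ccccn2)c2cc(Br)ccc2N1,hypnotic_anxiolytic,False
Lunesta,Eszopiclone,CN1CCN(CC1)C(=O)OC1c2nccnc2C(=O)N1c1ccc(Cl)cn1,hypnotic_anxiolytic,False
Depas,Etizolam,CCc1cc2c(s1)-n1c(C)nnc1CN=C2c1ccccc1Cl,hypnotic_anxiolytic,False
Belsomra,Suvorexant,CC1CCN(c2nc3cc(Cl)ccc3o2)CCN1C(=O)c1cc(C)ccc1-n1nccn1,hypnotic_anxiolytic,False
Paxil,Paroxetine,Fc1ccc(C2CCNCC2COc2ccc3OCOc3c2)cc1,antipsychotic,False
Lexapro,Escitalopram,CN(C)CCCC1(c2ccc(F)cc2)OCc2cc(C#N)ccc21,antipsychotic,False
Sertraline,Sertraline,CNC1CCC(c2ccc(Cl)c(Cl)c2)c2ccccc21,antipsychotic,False
Abilify,Aripiprazole,O=C1CCc2cc(OCCCCN3CCN(c4cccc(Cl)c4Cl)CC3)ccc2N1,antipsychotic,False
Contomin,Chlorpromazine,CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21,antipsychotic,False
Zyprexa,Olanzapine,Cc1cc2c(s1)Nc1ccccc1N=C2N1CCN(C)CC1,antipsychotic,False
Risperdal,Risperidone,Cc1nc2n(c1CCN1CCC(c3noc4cc(F)ccc34)CC1)CCCC2=O,antipsychotic,False
Restamin,Diphenhydramine,CN(C)CCOC(c1ccccc1)c1ccccc1,antiallergic,True
Medicon,Dextromethorphan,COc1ccc2c(c1)C13CCCCC1C(C2)N(C)CC3,antitussive,True
Zithromax,Azithromycin,CCC1OC(=O)C(C)C(OC2CC(C)(OC)C(O)C(C)O2)C(C)C(OC2OC(C)CC(N(C)C)C2O)C(C)(O)CC(C)CN(C)C(C)C(O)C1(C)O,antibiotic,False
Metformin,Metformin,CN(C)C(=N)NC(=N)N,antidiabetic,False
Lasix,Furosemide,NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl,diuretic,False
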