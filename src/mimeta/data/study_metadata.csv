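study_id,n_control,n_case,country,study_age,organism
GSE24519,4,34,Italy,3,Homo sapiens
GSE24591,4,34,Italy,3,Homo sapiens
GSE34198,48,49,Czechia Republic,6,Homo sapiens
GSE48060,21,31,United States,6,Homo sapiens
GSE60993,7,10,South Korea,5,Homo sapiens
GSE60993_2,7,17,South Korea,5,Homo sapiens
GSE62646,14,84,Poland,6,Homo sapiens
GSE66360,50,49,United States,5,Homo sapiens
GSE97320,3,3,China,3,Homo sapiens
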