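# Literature-derived regulators of myocardial infarction (MI) that are driven
# by schizophrenia (SCZ), transcribed from the published pathway networks.
# Every relationship carries at least three supporting references (min_refs).
# Counting note: published summary text counts five small molecules, but the
# small-molecule network itself contains six; this table follows the network
# content (six small molecules, 19 regulators in total).
name	level	mi_role	scz_effect	min_refs
IL6	gene	promoter	activates	3
CRP	gene	promoter	activates	3
ADIPOQ	gene	inhibitor	deactivates	3
SOD2	gene	inhibitor	deactivates	3
TXN	gene	inhibitor	deactivates	3
NGF	gene	inhibitor	deactivates	3
ADORA1	gene	inhibitor	deactivates	3
NOS1	gene	inhibitor	deactivates	3
CTNNB1	gene	inhibitor	deactivates	3
lipid peroxide	small_molecule	promoter	activates	3
superoxide	small_molecule	promoter	activates	3
arachidonic acid	small_molecule	promoter	deactivates	3
ATP	small_molecule	inhibitor	deactivates	3
ascorbic acid	small_molecule	inhibitor	deactivates	3
melatonin	small_molecule	inhibitor	deactivates	3
inflammatory cytokine	gene_family	promoter	activates	3
IL1 family	gene_family	promoter	activates	3
CaM kinase 2	complex	promoter	activates	3
IL23	complex	promoter	activates	3
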