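pmid	example_id	text	label	evidence_subtype
20303984	t1_negative	As the translational control in the expression of cycle proteins Cdc13 and Cdc25 constructs positive feedback loops, the dynamical activities of the key components undergoes a rapid rising after a preliminary stage of slow increase.	negative	n/a
16400179	t1_positive	In contrast, degradation of MTH1 is reinforced by glucose repression of MTH1 expression: disappearance of MTH1 is slowed when glucose repression of MTH1 expression is prevented, and this results in a delay in induction of HXT3 expression in response to glucose.	positive	direct
15546622	example_1	Endogenous Mdm2 is tethered in vivo, presumably via p53, to chromatin comprising the p53-responsive p21(waf1) promoter, and Mdm2 overexpression enhances protein ubiquitylation in the vicinity of a p53 binding site within that promoter.	positive	direct
20008511	example_2	Deletion of CHZ1 led to reduced ubiquitination of subtelomere-associated H2B, reduced subtelomeric H3K79 dimethylation, and increased binding of Sir3p, and Sir4p at telomere-distal euchromatin regions, correlating with decreased gene expression in subtelomeric regions.	positive	direct
21526151	example_3	The cofactor npl4-1 and ufd1-2 mutants also exhibit G1 delay and reduced CLN1 promoter activity at 38.5 degrees C, suggesting that Npl4-Ufd1 complex mediates the function of Cdc48 at G1.	positive	direct
12737807	example_4	We show here that the role of these proteins is instead to promote nucleolar segregation, including release of the Cdc14 phosphatase required for Cdk1 inactivation and disassembly of the anaphase I spindle.	negative	n/a
18408730	example_5	Here we show that two highly conserved ATP-dependent chromatin-remodeling complexes in Saccharomyces cerevisiae, Isw2 and Ino80, function in parallel to promote replication fork progression.	negative	n/a
16997274	example_6	Of the single codon changes, mutation of the first ATG (ATG1) resulted in the largest increase of the reporter gene PIS1(promoter)-lacZ expression.	negative	n/a
12086182	example_7	The results indicate that during the first hours of microvinification there is an increase in the GPDI mRNA levels with a maximum about one hour after inoculation, and a decrease in the amount of HSP12 and HSP104 mRNAs, although with differences between them.	positive	indirect_I
8483452	example_8	Four different conditions were found to cause expression of Ime1 protein in vegetative cultures: elevated transcription levels due to the presence of IME1 on a multicopy plasmid; elevated transcription provided by a Gal-IME1 construct; G1 arrest due to alpha-factor treatment; G1 arrest following mild heat-shock treatment of cdc28 diploids.	positive	indirect_II
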