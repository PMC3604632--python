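# db=Entrez Gene / UCSC Genome Browser
# version=July 2011
# build=Hg17|Hg18|Hg19
# access_date=unknown
GeneID	Symbol	Synonyms	Chromosome	Description	Hg17	Hg18	Hg19
9214	FAIM3	TOSO	1	Fas apoptotic inhibitory molecule 3	203466126-203483738	205144354-205161966	207076633-207095378
5284	PIGR	FLJ22667|MGC125361|MGC125362	1	Polymeric immunoglobulin receptor	203490267-203508202	205168495-205186430	207101869-207119811
83953	FCAMR	FCA/MR|FKSG87	1	Fc receptor, IgA, IgM, high affinity	Information Not available	205198027-205210593	207131404-207143970
148	ADRA1A	ADRA1C|ADRA1L1|ALPHA1AAR	8	Adrenergic, alpha-1A-, receptor	26683139-26778839	26683139-26778839	26627222-26722922
147	ADRA1B	ADRA1|ALPHA1BAR	5	Adrenergic, alpha-1B-, receptor	159276318-159332129	159276318-159332595	159343740-159400017
146	ADRA1D	ADRA1|ADRA1A|ADRA1R|ALPHA1|DAR|dJ779E11.2	20	Adrenergic, alpha-1D-, receptor	4149816-4177659	4149278-4177659	4201278-4229659
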