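# Census of cultivated rumen bacteria by phylum: number of genera with at
# least one cultured rumen representative, and number of rumen-origin
# isolates held across five international culture collections (ATCC, CCUG,
# DSMZ, JCM, BCCM/LMG).  Survey columns give species-level OTU counts per
# phylum from two 16S rRNA gene meta-analyses of the rumen microbiome.
phylum	cultured_genera	cultured_isolates	reference_survey_otus	this_survey_otus
Actinobacteria	11	25	107	41
Bacteroidetes	6	5	3605	907
Cyanobacteria	0	0	1	3
Fibrobacteres	1	7	112	16
Firmicutes	45	90	7797	1263
Fusobacteria	1	0	10	1
Planctomycetes	0	0	17	1
Proteobacteria	20	16	928	64
Spirochaetes	1	2	144	48
Synergistetes	1	1	382	11
Acidobacteria	0	0	1	3
Tenericutes	2	0	16	21
Chloroflexi	0	0	14	4
Deferribacteres	0	0	4	0
Lentisphaerae	0	0	12	2
Verrucomicrobia	0	0	57	1
OP10	0	0	1	0
SR1	0	0	32	4
TM7	0	0	39	14
Nitrospira	0	0	0	1
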