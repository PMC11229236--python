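gene_id	gene_name	abbreviation
PRUPE_1G290600	APETALA1	AP1
PRUPE_6G128400	CENTRORADIALIS-like	CEN
PRUPE_6G021200	Cyclin B1.2	CYCB1.2
PRUPE_4G269600	Cyclin B1.4	CYCB1.4
PRUPE_6G364900	FLOWERING LOCUS T	FT
PRUPE_4G150200	Gibberellin 2-oxidase 6	GA2ox6
PRUPE_3G161500	Gibberellin-regulated family protein RSI-1	RSI-1
PRUPE_4G204900	Polyubiquitin 10	UBQ10
PRUPE_6G256300	Squamosa Promoter binding protein-like 9.1	SPL9.1
PRUPE_7G074200	Squamosa Promoter binding protein-like 9.2	SPL9.2
PRUPE_7G112600	TERMINAL FLOWER1	TFL1
PRUPE_4G138900	Translation Elongation Factor 2	TEF2
PRUPE_5G176400	Trehalose Phosphate Synthase 9	TPS9
PRUPE_1G256200	Trehalose Phosphate Synthase 10	TPS10
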