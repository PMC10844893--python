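patient	sex	age	smoking	pathology	mutation
#1	Male	69	1	Acinar (50%), lepidic (50%)	EGFR (L858R)
#2	Female	77	0	Acinar (60%), lepidic (40%)	RET fusion
#3	Female	62	0	Acinar (80%), lepidic (10%), micropapillary (10%)	EGFR (L858R)
#4	Female	65	0	Acinar (40%), lepidic (60%)	EGFR (L858R)
#5	Female	72	0	Acinar (55%), lepidic (40%), micropapillary (5%)	EGFR (L858R)
#6	Male	65	1	Acinar (50%), lepidic (40%), complex glandular structures (10%)	KRAS (G12D)
#7	Female	69	0	Acinar (80%), lepidic (10%), micropapillary (10%)	EGFR (L858R)
#8	Female	59	0	Acinar (60%), lepidic (20%), complex glandular structures (10%), micropapillary (10%)	EGFR (19Del)
#9	Male	69	1	Acinar (80%), lepidic (20%)	EGFR (19Del)
#10	Male	53	0	Acinar (80%), lepidic (20%)	EGFR (19Del)
#11	Male	41	0	Acinar (90%), lepidic (10%)	EGFR (L858R)
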