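sample_id	diagnosis	age	sex	pmi	doi	cpeq	cause_of_death
S01	SCZ	68	Female	15.0	40	NA	Chronic renal failure
S02	SCZ	71	Male	16.5	48	NA	Pneumonia
S03	SCZ	79	Female	17.0	60	NA	Leukocytoclastic
C01	CON	85	Female	8.0	0	0	Pneumonia
C02	CON	89	Female	4.0	0	0	Heart failure
C03	CON	66	Male	42.0	0	0	Sudden death
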