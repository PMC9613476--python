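case_id	sex	age	age_group	phenotype	notch_fbxw7	primary_event	cth_event	additional_events	epigenetic_alterations
1	F	27	adult	ETP	mutated	SET-NUP214	arr(5q)cth	TCF7 del;SEC63 del;WT1 del;ATM del;TP53 del;RB1 del
2	M	19	adult	near-ETP	mutated	SET-NUP214	arr(1,17)cth	CASP8AP2-GRIK2-SEC63 del;WT1 del;ETV6-CDKN1B del;RB1 del;TP53 del;NF1-SUZ12 del	SUZ12 del
3	M	30	adult	ETP	wild-type	SET-NUP214	arr(16)cth	TCF7 del;WT1 del;ETV6-CDKN1B del;NF1-SUZ12 del	EZH2 mut;SUZ12 del
4	M	20	adult	ETP	wild-type	SQSTM1-NUP214	arr(13q)cth	terminal 5q del;CDKN2AB del;WT1 del;NF1-SUZ12 del	SUZ12 del
5	M	32	adult	ETP	mutated	TRB-HOXA	arr(6,7,9)cth	TCF7 del;CASP8AP2 del;CDKN2AB del;trisomy 8
6	F	19	adult	ETP	mutated	TRB-HOXA	arr(6,8)cth	GRIK2-SEC63-FYN del;MYB gain;PIM1 translocation;CDKN2AB del;trisomy 20;trisomy 21	EZH2 mut
7	M	34	adult	ETP	mutated	TRB-HOXA	arr(7)cth	LCK-TAL1-SIL-JAK1 gain	EZH2 mut
8	M	22	adult	near-ETP	wild-type	Mir181-HOXA	arr(12,17,18,20)cth	TCF7 del;ETV6-CDKN1B del;RB1-DLEU1-DLEU7 del;TP53 del;NF1-SUZ12 del	SUZ12 del
9	M	37	adult	ETP	wild-type	PICALM-MLLT10	arr(2,6)cth	TCF7 del;CASP8AP2-GRIK2 del;MYC gain;CDKN2AB del;ATM del
10	M	24	adult	ETP	wild-type	undetermined	arr(7)cth	GRIK2-SEC63-FYN del;TRB del;CDKN2AB del;ETV6-CDKN1B del
11	M	23	adult	ETP	mutated	undetermined	arr(1p)cth	IKZF1 del;ETV6-CDKN1B del;RB1-DLEU1-DLEU7 del;NF1-SUZ12 del	ASXL1 mut;SUZ12 del
12	F	62	adult	ETP	mutated	undetermined	arr(1p)cth	TCF7 del;CASP8AP2-GRIK2-SEC63-FYN del;ETV6-CDKN1B del;RB1-D13S319 del;NF1-SUZ12 del	DNMT3A mut;SUZ12 del
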