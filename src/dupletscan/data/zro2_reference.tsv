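Sequence	NegativeAA	PositiveAA	Duplet	NetChargePH7	pI
APSQPKDEVTAY	2	1	Yes	-1	4.37
NPTLHQERMQDW	2	1	Yes	-1	5.32
DLNYFTLSSKRE	2	2	Yes	0	6.07
ILSTQDLKAKSS	1	2	No	1	8.59
HYPTAKFHAERL	1	2	Yes	1	8.60
NLPKRDGWPLPW	1	2	Yes	1	8.75
YSLRADSRWMPS	1	2	No	1	8.75
FHEKQLSGGRFG	1	2	Yes	1	8.76
AIMGPRTVDRLP	1	2	Yes	1	9.60
IHSLQPEVNVRR	1	2	No	1	9.61
QHVYHPKPKASR	0	3	No	3	10.29
HLPQKKKPPHAI	0	3	No	3	10.30
HLPQKKKPPHAM	0	3	No	3	10.30
NKWPLAHSQKKR	0	4	No	4	11.26
KKRRRPSMYVPI	0	5	No	5	11.73
RKKTPASRRPMR	0	6	No	6	12.48
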