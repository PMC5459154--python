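Sequence	NegativeAA	PositiveAA	Duplet	NetChargePH7	pI
ERSWTLDSALSM	2	1	Yes	-1	4.37
MKPDKAIRLDLL	2	3	Yes	1	8.59
HYPTAKFHAERL	1	2	Yes	1	8.60
HHTHRVDVHQTR	1	2	No	1	9.62
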