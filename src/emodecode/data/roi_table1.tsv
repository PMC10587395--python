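name	part	size	x	y	z
FFA	-	1784	39	-52	-26
EV	-	4248	-12	-94	-8
EBA	-	5488	45	-67	7
A1	L	6152	-57	-17	5
A1	R	6152	56	-17	8
MPFC	-	2976	11	48	17
pSTS	-	3256	-47	-62	8
Amygdala	L	784	-21	-6	-10
Amygdala	R	784	20	-6	-9
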