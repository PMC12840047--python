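sample_code	variety	aroma_type
652	Nanjing46	A
953	Daohuaxiang	A
574	Kongyu131	B
429	Suijing18	C
691	jasmine rice	C
724	Longyang16	A
860	Suxiu	B
836	Taixiangjing1402	B
398	Jihong6	C
560	Ningxiangjing9	C
951	Zhongkefa5	B
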