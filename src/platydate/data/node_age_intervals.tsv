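node	rate_fast	rate_slow	t_fast	t_slow	gbar
Crown Platyrrhini	8.5E-10	6.06E-10	20.31	28.49	16.0
Atelidae branching	8.5E-10	6.06E-10	19.05	26.72	16.0
Crown Cebidae	9.07E-10	6.47E-10	15.56	21.81	15.0
Crown Anthropoidea	8.5E-10	6.06E-10	36.88	51.73	16.0
Crown Catarrhini	6.97E-10	4.97E-10	24.29	34.06	19.5
Homo/Pan	5.04E-10	3.59E-10	7.31	10.26	27.0
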