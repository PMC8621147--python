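name	hla	sequence	deamidation_mask
DQ2.5-glia-γ1	DQ2.5	PQQSFPQQQ
DQ2.5-glia-γ2	DQ2.5	IQPQQPAQL
DQ2.5-glia-γ3	DQ2.5	QQPQQPYPQ
DQ2.5-glia-γ4b	DQ2.5	PQPQQQFPQ
DQ2.5-glia-γ4c	DQ2.5	QQPQQPFPQ
DQ2.5-glia-γ5	DQ2.5	QQPFPQQPQ
DQ2.5-glia-ω1	DQ2.5	PFPQPQQPF
DQ8-glia-γ1a	DQ8	QQPQQPFPQ
DQ8-glia-γ1b	DQ8	QQPQQPYPQ
DQ8.5-glia-γ1	DQ8.5	PQQSFPQQQ
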