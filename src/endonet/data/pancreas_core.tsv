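source	target	sign
PDX1	PDX1	+1
PTF1A	PTF1A	+1
NKX6.1	NKX6.1	+1
SOX9	SOX9	+1
SOX9	HES1	+1
NGN3	NGN3	+1
NGN3	ARX	+1
NGN3	PAX4	+1
PAX4	PDX1	+1
ARX	PDX1	-1
NKX6.1	PTF1A	-1
NGN3	PTF1A	-1
PDX1	NKX6.1	+1
PTF1A	NKX6.1	-1
ARX	NKX6.1	-1
NGN3	SOX9	-1
PDX1	NGN3	+1
SOX9	NGN3	+1
HES1	NGN3	-1
PTF1A	NGN3	-1
PAX4	ARX	-1
ARX	PAX4	-1
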