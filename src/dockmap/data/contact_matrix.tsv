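# Symmetric atom-type contact energies (dimensionless, negative = attractive).
# Columns/rows follow the header order.
	C_aliph	C_arom	N_don	O_acc	S	P	other
C_aliph	-0.40	-0.35	-0.05	-0.05	-0.30	-0.05	-0.10
C_arom	-0.35	-0.45	-0.10	-0.10	-0.30	-0.05	-0.10
N_don	-0.05	-0.10	0.15	-0.80	-0.05	-0.10	-0.10
O_acc	-0.05	-0.10	-0.80	0.15	-0.05	-0.10	-0.10
S	-0.30	-0.30	-0.05	-0.05	-0.25	-0.05	-0.10
P	-0.05	-0.05	-0.10	-0.10	-0.05	0.10	-0.10
other	-0.10	-0.10	-0.10	-0.10	-0.10	-0.10	-0.10
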