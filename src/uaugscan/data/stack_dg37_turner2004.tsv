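# parameter_set_id	turner2004
# duplex_init	4.10
# terminal_au	0.50
doublet	dg37
AA/UU	-0.90
AU/UA	-1.10
AC/UG	-2.20
AG/UC	-2.10
AG/UU	-0.60
AU/UG	-1.40
UA/AU	-1.30
UU/AA	-0.90
UC/AG	-2.40
UG/AC	-2.10
UG/AU	-1.00
UU/AG	-1.30
CA/GU	-2.10
CU/GA	-2.10
CC/GG	-3.30
CG/GC	-2.40
CG/GU	-1.40
CU/GG	-2.10
GA/CU	-2.40
GU/CA	-2.20
GC/CG	-3.40
GG/CC	-3.30
GG/CU	-1.50
GU/CG	-2.50
GA/UU	-1.30
GU/UA	-1.40
GC/UG	-2.50
GG/UC	-2.10
GG/UU	-0.50
GU/UG	1.30
UA/GU	-1.00
UU/GA	-0.60
UC/GG	-1.50
UG/GC	-1.40
UG/GU	0.30
UU/GG	-0.50
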