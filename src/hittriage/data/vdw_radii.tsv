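# van der Waals radii (Angstrom), Bondi 1964 with common extensions
# element	radius
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
Cl	1.75
Br	1.85
I	1.98
B	1.92
Se	1.90
Zn	1.39
Mg	1.73
Na	2.27
K	2.75
Ca	2.31
Fe	1.94
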