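# contactsurf radii table, version 1
# name: mol2-typed
# Explicit-hydrogen van der Waals radii (Angstrom) keyed on SYBYL atom
# types, following the fine-grained standard-radii scheme used by common
# molecular-modelling software (Tsai-1999/Chimera-style values).
# Line formats:
#   <SYBYL-TYPE> <radius>
#   ELEM <ELEMENT> <radius>         fallback on the element before the dot
#   FALLBACK <radius>
C.3 1.88
C.2 1.76
C.1 1.78
C.ar 1.77
C.cat 1.76
N.4 1.64
N.3 1.64
N.2 1.64
N.1 1.60
N.ar 1.64
N.am 1.64
N.pl3 1.64
O.3 1.46
O.2 1.42
O.co2 1.42
O.spc 1.46
O.t3p 1.46
S.3 1.77
S.2 1.77
S.o 1.77
S.o2 1.77
P.3 1.88
H 1.00
H.spc 1.00
H.t3p 1.00
F 1.47
Cl 1.75
Br 1.85
I 1.98
Li 1.82
Na 2.27
K 2.75
Mg 1.73
Ca 2.31
Zn 1.39
Fe 1.47
ELEM C 1.80
ELEM N 1.64
ELEM O 1.46
ELEM S 1.77
ELEM P 1.88
ELEM H 1.00
FALLBACK 1.70
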