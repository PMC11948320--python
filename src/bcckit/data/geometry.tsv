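# Standard internal-coordinate constants for chain-conformer construction
# and fixture embedding.  Bond lengths in Angstrom; unlisted pairs fall
# back to the sum of covalent radii.  Bend angles default to tetrahedral
# (109.471 deg) at sp3 centers.
# elem_a	elem_b	length_A
C	C	1.53
C	O	1.43
C	H	1.09
O	H	0.96
C	N	1.47
N	H	1.01
C	S	1.81
S	H	1.34
C	F	1.35
C	Cl	1.77
C	Br	1.94
C	I	2.14
C	P	1.84
P	H	1.42
O	O	1.48
N	N	1.45
N	O	1.40
O	P	1.60
O	S	1.57
S	S	2.05
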