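# Default atom-type perception rules (ordered, first match wins).
# SYNTHETIC STAND-IN vocabulary: the distinctions mirror those the AM1-BCC
# charge-model family draws (aromatic vs aliphatic carbon, hydroxyl vs
# ether vs carbonyl oxygen, ...) but the codes and the companion correction
# table are this package's own and carry no published parameter values.
# Columns: element  degree  aromatic  ring_size  neighbors  type_code
# "*" = unconstrained; neighbors = comma-separated required neighbor elements.
H	1	*	*	O	ho
H	1	*	*	N	hn
H	1	*	*	S	hs
H	1	*	*	P	hp
H	*	*	*	*	hc
C	*	yes	*	*	ca
C	3	*	*	O	c
C	4	*	*	*	c3
C	3	*	*	*	c2
C	2	*	*	*	c1
C	*	*	*	*	c3
N	*	yes	*	*	na
N	3	*	*	O,O	no
N	1	*	*	*	n1
N	2	*	*	*	n2
N	*	*	*	*	n3
O	*	yes	*	*	oa
O	1	*	*	*	o
O	2	*	*	H	oh
O	*	*	*	*	os
S	*	yes	*	*	sa
S	1	*	*	*	s
S	2	*	*	H	sh
S	3	*	*	*	s3
S	*	*	*	*	ss
P	4	*	*	*	p4
P	*	*	*	*	p3
F	*	*	*	*	f
Cl	*	*	*	*	cl
Br	*	*	*	*	br
I	*	*	*	*	i
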