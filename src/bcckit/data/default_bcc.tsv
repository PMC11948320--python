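# Default bond-charge-correction table.
# SYNTHETIC STAND-IN values in elementary charge units: structurally
# analogous to the AM1-BCC family (small signed per-bond-type transfers)
# but NOT a released parameter set.  Sign convention: the value is added to
# the atom carrying type_a (first code in canonical, lexicographic order)
# and subtracted from the type_b atom.
# type_a	type_b	bond_class	value_e
c3	hc	single	0.020
c2	hc	single	0.015
c1	hc	single	0.012
ca	hc	single	0.014
c	hc	single	0.026
c3	oh	single	-0.061
ca	oh	single	-0.052
ho	oh	single	0.072
c	o	double	-0.140
c	os	single	-0.070
c3	os	single	-0.055
c	oh	single	-0.080
c	c3	single	-0.022
c2	c3	single	-0.010
c1	c3	single	-0.018
c3	ca	single	0.008
c3	n3	single	-0.040
hn	n3	single	0.100
c	n3	single	-0.095
hn	na	single	0.110
ca	na	aromatic	-0.030
c3	f	single	-0.075
c3	cl	single	-0.045
c3	br	single	-0.035
c3	i	single	-0.020
ca	cl	single	-0.040
c3	ss	single	-0.020
hs	sh	single	0.045
c3	sh	single	-0.018
c	o	delocalized	-0.110
no	o	delocalized	-0.120
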