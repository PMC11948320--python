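# Electronegativity-equalization (EEM) per-element parameters.
# SYNTHETIC STAND-IN values: electronegativities chi are Mulliken-style
# averages (V); hardnesses eta (V/e) are inflated relative to gas-phase
# atomic hardness so the coupled linear system stays well conditioned at
# bonded distances with the Coulomb constant kappa = 14.4 V*A/e.
# These are not a published EEM parameterization.
# element	chi_V	eta_V_per_e
H	7.18	18.0
C	6.27	14.0
N	7.27	15.0
O	7.54	16.0
F	10.41	19.0
P	5.62	13.0
S	6.22	13.0
Cl	8.29	15.0
Br	7.59	14.0
I	6.76	13.0
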