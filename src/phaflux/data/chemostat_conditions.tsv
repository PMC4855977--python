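# Growth kinetics and stoichiometry under carbon (glycerol) and nitrogen
# (ammonium) limitation.  Rates in mmol gCDW^-1 h^-1; y_xs_residual is the
# biomass yield excluding PHA (g g^-1); pha_fraction is the PHA weight
# fraction of CDW.  Organic-acid rates reported as "not detected" (< 0.1)
# are entered as 0.
condition	limitation	dilution_rate	residual_ammonium	residual_glycerol	y_xs_residual	pha_fraction	q_glycerol_mmol	q_malate	q_succinate	q_co2	q_co2_sd
C-lim-low	carbon	0.044	68.2	NA	0.47	0.025	1.02	0	0	1.5	0.1
N-lim-low	nitrogen	0.044	NA	19.9	0.19	0.297	2.47	0.04	0.24	3.6	0.1
C-lim-high	carbon	0.120	35.1	NA	0.51	0.027	2.60	0	0	3.2	0.1
N-lim-high	nitrogen	0.120	NA	25.7	0.34	0.128	3.71	0.21	0	4.2	0.1
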