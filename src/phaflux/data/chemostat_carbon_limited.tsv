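condition	limitation	dilution_rate	biomass	q_glycerol_mass	pha_fraction
C-lim-D0.044	carbon	0.044	1.91	0.095	NA
C-lim-D0.066	carbon	0.066	1.93	0.137	NA
C-lim-D0.088	carbon	0.088	2.03	0.168	NA
C-lim-D0.109	carbon	0.109	2.08	0.215	NA
C-lim-D0.120	carbon	0.120	2.08	0.237	NA
C-lim-D0.141	carbon	0.141	2.01	0.288	NA
C-lim-D0.190	carbon	0.190	2.10	0.390	NA
C-lim-D0.210	carbon	0.210	2.11	0.410	NA
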