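# Central carbon metabolism of Pseudomonas putida KT2440 growing on glycerol,
# transcribed reaction-per-reaction from the published appendix table, including
# its typographic quirks (one missing closing bracket, parenthesized
# coefficients); the parser normalizes both.
# Species tokens keep the printed names; subscript markup is written plain
# (CO2, NH3, SO4, O2).

[pathway: Transport reactions]
EX_glycerol: → GLY[e]
EX_nh3: → NH3[c]
EX_so4: → SO4[c]
EX_o2: → O2[c]
EX_biomass: biomass[c] →
EX_formate: FORMATE_ex[e] →
EX_malate: MAL_ex[e] →
EX_succinate: SUCC_ex[e] →
EX_pha: PHA[c] →
EX_atp_maintenance: ATPmaintenance[c] →
EX_co2: CO2[c] →

[pathway: Glycerol uptake and conversion to glycerone-phosphate]
glyt_outer: GLY[e] → GLY[p]
glyt_inner: GLY[p] → GLY[c]
glpK: GLY[c] + ATP[c → GLY-3P[c] + ADP[c]
glpD: GLY-3P[c] + NAD[c] ↔ DHAP[c] + NADH[c]

[pathway: Pentose phosphate pathway]
zwf: G6P[c] + NADP[c] → 6-P-Gluconate[c] + NADPH[c]
gnd: 6-P-Gluconate[c] + NADP[c] → RIB-5P[c] + CO2[c] + NADPH[c]
rpe: RIB-5P[c] ⟺ XYL-5P[c]
rpi: RIB-5P[c] ⟺ RIBO-5P[c]
tktA: S7P[c] + GAP[c] ⟺ RIBO-5P[c] + XYL-5P[c]
tal: S7P[c] + GAP[c] ⟺ E4P[c] + F6P[c]
tktB: F6P[c] + GAP[c] ⟺ E4P[c] + XYL-5P[c]

[pathway: Entner-Doudoroff pathway]
edd: 6-P-Gluconate[c] → KDPG[c]
eda: KDPG[c] → GAP[c] + PYR[c]

[pathway: Embden-Meyerhof-Parnas pathway]
pgi: G6P[c] ⟺ F6P[c]
fbp: FBP[c] → F6P[c]
fda: FBP[c] ⟺ GAP[c] + DHAP[c]
tpi: DHAP[c] ⟺ GAP[c]
gap: GAP[c] + NAD[c] ⟺ 13-PG[c] + NADH[c]
pgk: ADP[c] + 13-PG[c] ⟺ ATP[c] + 3-PG[c]
pgm: 3-PG[c] ⟺ 2-PG[c]
eno: 2-PG[c] ⟺ PEP[c]
pyk: PEP[c] + ADP[c] → PYR[c] + ATP[c]
pdh: PYR[c] + NAD[c] → AcCoA[c] + NADH[c] + CO2[c]
pps: PYR[c] + 2 ATP[c] → 2 ADP[c] + PEP[c]

[pathway: Citric acid cycle]
gltA: AcCoA[c] + OAA[c] → CIT[c]
acnA: CIT[c] ↔ ICI[c]
icd: ICI[c] + NADP[c] → AKG[c] + CO2[c] + NADPH[c]
sucAB: AKG[c] + NAD[c] → SUCC-CoA[c] + NADH[c] + CO2[c]
sucCD: SUCC-CoA[c] + ADP[c] ↔ SUCC[c] + ATP[c]
sdh: SUCC[c] + Q[c] ↔ FUM[c] + QH2[c]
fum: FUM[c] ↔ MAL[c]
mdh: MAL[c] + NAD[c] ↔ OAA[c] + NADH[c]

[pathway: Organic acid production]
mal_sec: MAL[c] → MAL_ex[e]
succ_sec: SUCC[c] → SUCC_ex[e]
formate_sec: FORMATE[c] → FORMATE_ex[e]

[pathway: Glyoxylate metabolism]
aceA: ICI[c] → Glyoxy[c] + SUCC[c]
aceB: Glyoxy[c] + AcCoA[c] → MAL[c]

[pathway: Amphibolic metabolism]
oad: OAA[c] → PYR[c] + CO2[c]
ppc: PEP[c] + CO2[c] + ATP[c] → OAA[c] + ADP[c]
mae: MAL[c] + NADP[c] → PYR[c] + NADPH[c] + CO2[c]

[pathway: PHA production]
phaC10: 5 AcCoA[c] + 4 ATP[c] + 7 NADPH[c] → C10-PHA[c] + 4 ADP[c] + 7 NADP[c]
phaC8: 4 AcCoA[c] + 4 ATP[c] + 7 NADPH[c] → C8-PHA[c] + 4 ADP[c] + 7 NADP[c]
phaC12: 6 AcCoA[c] + 4 ATP[c] + 7 NADPH[c] → C12-PHA[c] + 4 ADP[c] + 7 NADP[c]
pha_lump: 0.75 C10-PHA[c] + 0.17 C8-PHA[c] + 0.08 C12-PHA[c] → PHA[c]

[pathway: Energy metabolism]
udhA: NADPH[c] + NAD[c] → NADP[c] + NADH[c]
pntAB: (3) NADH[c] + (3) NADP[c] + ATP[c] → (3) NAD[c] + (3) NADPH[c] + ADP[c]
nuo: (0.5) O2[c] + NADH[c] + (1.33) ADP[c] → NAD[c] + (1.33) ATP[c]
cyo: (0.5) O2[c] + QH2[c] + (0.66) ADP[c] → Q[c] + (0.66) ATP[c]
atp_maint: ATP[c] → ADP[c] + ATPmaintenance[c]
cys_syn: SO4[c] + (3) NADPH[c] + (4) ATP[c] → H2S[c] + (3) NADP[c] + (4) ADP[c]

[pathway: Biomass production]
biomass_syn: (1.481) OAA[c] + (1.338) 3-PG[c] + (0.627) RIBO-5P[c] + (17.821) ATP[c] + (16.548) NADPH[c] + (6.965) NH3[c] + (3.548) NAD[c] + (2.930) AcCoA[c] + (2.861) PYR[c] + (1.078) AKG[c] + (0.361) E4P[c] + (0.72) PEP[c] + (0.233) H2S[c] + (0.072) F6P[c] + (0.206) G6P[c] + (0.129) GAP[c] → biomass[c] + (16.548) NADP[c] + (3.548) NADH[c] + (17.821) ADP[c] + (1.678) CO2[c]
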