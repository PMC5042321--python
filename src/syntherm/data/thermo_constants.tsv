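kind	name	value	n_electrons	phase	charge	oxidized	reduced	source
compound	H2O	-237.17		water	0			Thauer1977
compound	H+	-39.96		proton	1			pH7-convention RT*ln(1e-7)
compound	H2	0.0		gas	0			Thauer1977
compound	CO2	-394.36		gas	0			Thauer1977
compound	CH4	-50.75		gas	0			Thauer1977
compound	lactate	-517.81		solute	-1			Thauer1977
compound	pyruvate	-474.63		solute	-1			Thauer1977
compound	formate	-351.04		solute	-1			Thauer1977
compound	acetate	-369.41		solute	-1			Thauer1977
compound	ethanol	-181.75		solute	0			Thauer1977
compound	acetaldehyde	-139.9		solute	0			Thauer1977
compound	sulfite	-486.6		solute	-2			Thauer1977
compound	HS-	12.05		solute	-1			Thauer1977
compound	sulfate	-744.63		solute	-2			Thauer1977
compound	alanine			solute	0			no-consistent-dGf
compound	NH4+			solute	1			no-consistent-dGf
compound	acetyl-CoA			solute	0			thioester-not-tabulated
compound	CoA			solute	0			thioester-not-tabulated
compound	APS			solute	-2			nucleotide-not-tabulated
compound	AMP			solute	-2			nucleotide-not-tabulated
couple	pyruvate/lactate	-0.190	2			pyruvate:1;H+:2	lactate:1	Thauer1977
couple	H+/H2	-0.414	2			H+:2	H2:1	Thauer1977
couple	CO2/formate	-0.432	2			CO2:1;H+:1	formate:1	Thauer1977
couple	acetyl-CoA+CO2/pyruvate	-0.498	2			acetyl-CoA:1;CO2:1;H+:1	pyruvate:1;CoA:1	Thauer1977
couple	APS/AMP+sulfite	-0.060	2			APS:1;H+:1	AMP:1;sulfite:1	Thauer1977
couple	sulfite/HS-	-0.116	6			sulfite:1;H+:7	HS-:1;H2O:3	Thauer1977
couple	acetaldehyde/ethanol	-0.197	2			acetaldehyde:1;H+:2	ethanol:1	Thauer1977
couple	pyruvate+NH4+/alanine	-0.132	2			pyruvate:1;NH4+:1;H+:2	alanine:1;H2O:1	Thauer1977
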