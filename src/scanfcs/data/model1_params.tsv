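name	value	units	provenance	description
k1	500.0	au/hr	chosen	constitutive SHR production in the vasculature
D1	2.45	um^2/s	measured	SHR diffusion coefficient, vasculature+endodermis (RICS)
A1	100.0	um^2	chosen	mean vascular cell area (image-derived config input)
D2	2.40	um^2/s	measured	SHR diffusion coefficient in the SCR-knockdown endodermis (RICS)
A2	150.0	um^2	chosen	mean endodermal cell area (image-derived config input)
d1	1.0	1/hr	chosen	degradation of vascular SHR
d2	2.0	1/hr	estimated	degradation of endodermal SHR monomer (calibration target)
d3	0.6	1/hr	chosen	degradation of the SHR homodimer
L	0.5	au^-1/hr	measured	maximum homodimer formation rate (logistic ceiling; calibration target)
k	0.1	1/au	measured	steepness of the logistic homodimer switch
C0	360.0	au	measured	SCR threshold of the homodimer switch (60% of SCR steady state)
k3	260.0	au/hr	chosen	maximum SCR production (held fixed during calibration)
d4	0.35	1/hr	chosen	SCR degradation (held fixed during calibration)
K1D	10.0	au	chosen	dissociation constant of SHR-SCR binding in the SCR promoter logic
K2D	90.0	au	estimated	dissociation constant of the SCR autoregulatory logic (calibration target)
k4	0.002	1/(au hr)	chosen	association of SHR monomer with SCR (1:1 complex)
k5	0.004	1/(au hr)	derived	association of SHR homodimer with SCR (2:1 complex); 2x k4 statistical factor
d5	0.6	1/hr	chosen	degradation of the 1:1 complex
d6	0.54284	1/hr	derived	degradation of the 2:1 complex; fixed by the measured complex stoichiometry (see docs/methods.md)
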