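# Nearest-neighbor molar extinction coefficients for single-stranded RNA
# at 260 nm, pH 7, in M^-1 cm^-1.
# Sources: dinucleoside-monophosphate and nucleoside values tabulated by
# Richards (Handbook of Biochemistry, 1975) as compiled in Puglisi &
# Tinoco, Methods Enzymol. 180 (1989) 304-325. These are literature
# inputs, version 1 of this file; they are not fitted or asserted by this
# package.
# kind	key	eps_260
mono	A	15400
mono	C	7400
mono	G	11500
mono	U	9900
dimer	AA	13700
dimer	AC	10600
dimer	AG	12500
dimer	AU	12400
dimer	CA	10600
dimer	CC	7300
dimer	CG	9000
dimer	CU	8700
dimer	GA	12600
dimer	GC	8800
dimer	GG	10800
dimer	GU	10000
dimer	UA	12500
dimer	UC	8600
dimer	UG	9500
dimer	UU	8100
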