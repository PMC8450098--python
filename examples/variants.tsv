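# Motif duplex variants studied by UV melting (13-position template:
# left strand positions 1-7, right strand 8-13, both 5'->3').
id	left_strand_5to3	right_strand_5to3
#1_prototype	CUAGUAG	CGAACG
#2_U2C	CCAGUAG	CGAACG
#4_U2G	CGAGUAG	CGAACG
#8_G4A	CUAAUAG	CGAACG
#9_G4C	CUACUAG	CGAACG
#10_U2G/C12A	CGAGUAG	CGAAAG
#11_U2A/C12A	CAAGUAG	CGAAAG
#12_U2G/G9A/C12A	CGAGUAG	CAAAAG
#15_U2G/A6C/G9U/C12A	CGAGUCG	CUAAAG
#16_U2G/A6C/C12A	CGAGUCG	CGAAAG
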