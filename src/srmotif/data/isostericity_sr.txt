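# Curated isostericity matrices for the basepair families of the
# sarcin/ricin motif, version 1.
#
# One 4x4 grid per Leontis-Westhof family. The row base uses the first
# edge of the family tag, the column base the second (e.g. in [tHS] the
# row base pairs through its Hoogsteen edge, the column base through its
# Sugar edge). Families with swapped member order (tSH, tHW, cHS) are
# derived by transposition and are not stored separately.
#
# Cell values:
#   i1..i6    isosteric group of the pair
#   i1/i2     combined group
#   near:iN   near-isosteric to group iN
#   modeled:iN  modeled interaction, not yet observed at high resolution
#   -         base combination does not form this family (not a pair)
#
# Provenance: group assignments are compiled from the base combinations
# observed in a non-redundant survey of S/R motif instances in atomic-
# resolution rRNA structures, interpreted against the published
# isostericity classification of non-Watson-Crick families (Leontis,
# Stombaugh & Westhof, NAR 2002; Stombaugh et al., NAR 2009).
# Combinations never observed to form the family in any 3D structure are
# left unshaded ("-"). Cells whose group is not pinned down by an
# explicit observation are also "-" rather than guessed.

[tHS]
# row: Hoogsteen-edge base; column: Sugar-edge base.
# i1 is the large sheared-pair group (A-G and its isosteric partners,
# including the pairs observed at the lower tSH slot after member-order
# reversal: sugar/Hoogsteen AG, AA, UC, CC, AC, UA). G-G forms a tHS
# pair but belongs to its own group i2. C-G never forms tHS.
.	A	C	G	U
A	i1	-	i1	i1
C	i1	i1	-	i1
G	i1	-	i2	-
U	-	-	-	-

[tWH]
# row: Watson-Crick-edge base; column: Hoogsteen-edge base.
# U-A (reverse Hoogsteen) and C-C are isosteric (one group).
.	A	C	G	U
A	-	-	-	-
C	-	i1	-	-
G	-	-	-	-
U	i1	-	-	-

[tHH]
# Symmetric family (table equals its transpose).
# A-A is the prevalent combination; A-C occurs in most eubacterial
# large-subunit motifs; G-A is a rare variant observed in one archaeal
# context and is classified near-isosteric to the A-A/A-C group.
.	A	C	G	U
A	i1	i1	near:i1	-
C	i1	-	-	-
G	near:i1	-	-	-
U	-	-	-	-

[cSH]
# row: Sugar-edge base (the bulged nucleotide); column: Hoogsteen-edge
# base. The conserved bulged G pairs with the triple U (group i1).
# Bulged A, C and U occur at the same position but lose the triple
# contacts (base flipped out), so they form their own group i2.
.	A	C	G	U
A	-	-	-	i2
C	-	-	-	i2
G	-	-	-	i1
U	-	-	-	i2

[cWW]
# Symmetric family. i1: canonical Watson-Crick; i2: G-U wobble;
# i3: C-A(+); i4: pyrimidine-pyrimidine cWW pairs, all observed as
# S/R flanking pairs.
.	A	C	G	U
A	-	i3	-	i1
C	i3	i4	i1	i4
G	-	i1	-	i2
U	i1	i4	i2	i4
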