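# Two-residue PPR recognition code: the amino acid at motif position 5 and the
# last motif position jointly determine which nucleotide(s) a P/L/S motif
# preferentially binds. Compiled by hand from the canonical published
# combinations for PLS-class editing factors; this asset is a replaceable
# stand-in for any larger empirical code dataset (same dialect: one row per
# residue pair, nucleotides as a string over ACGU, "." = explicit
# no-prediction). Pairs absent from the table score as non-matching.
aa5	aa_last	nucleotides
T	D	G
T	N	A
T	S	A
S	N	A
S	D	G
S	S	A
G	N	A
G	D	U
N	D	U
N	N	CU
N	S	C
N	T	C
R	D	G
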