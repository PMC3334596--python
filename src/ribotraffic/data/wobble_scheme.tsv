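# Codon:anticodon pairing scheme for the tRNA adaptation index, one row per
# codon-third-position : anticodon-34 pairing class (dos Reis scheme).
# kind WC = Watson-Crick decoder, wobble = non-WC decoder reachable by wobble.
# initial_s are the published starting selective-constraint penalties.
codon3	anticodon34	label	kind	initial_s
T	A	I:U	WC	0.0
T	G	G:U	wobble	0.41
C	G	G:C	WC	0.0
C	A	I:C	wobble	0.28
A	T	U:A	WC	0.0
A	A	I:A	wobble	0.9999
G	C	C:G	WC	0.0
G	T	U:G	wobble	0.68
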