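# Curated granulin protein module structures and gene exon structures across taxa.
# One row per gene form: species, form, protein_structure, exon_structure.
# The Branchiostoma floridae row of the source compilation uses a prime/|nc|
# notation for single cysteines split across exon boundaries and an exon count
# that is itself uncertain; that notation is outside the grammar and the row is
# deliberately not included here.
species	form	protein_structure	exon_structure
Mammal	-	p-g*-g-g-g-g-g-g	sn-n*-c*-n-c-n-c-n-cn-cn-cn-c
Anolis carolinensis	-	p-g*-g-g-g-g-g-g-g-g	sn-n*-c*-n-c-n-c-n-cn-cn-cn-cn-cn-c
Xenopus tropicalis	-	p-g*-g-g-g-g-g-g-g-g-g-g-g-g-p-g	sn-n*-c*-n-c-n-c-n-c-n-c-n-c-n-c-n-c-n-c-n-c-n-c-n-c-n-cn-n-c
Danio rerio	GrnA	g-g*-g-g-g-g-g-g-g-g-g-g	sn-c-n*-c*-n-c-y-n-c-n-c-n-c-n-c-n-c-n-cn-cn-cn-c
Danio rerio	GrnB	g-g-g-g-g-g-g-g-g	sn-c-n-c-y-n-c-n-cn-cn-cn-cn-cn-c
Danio rerio	Grn1,2	g-p	sn-c-n
Petromyzon marinus	L	g-g-g-g-g-g-g-g-g-g	sn-c-n-cn-cn-cn-cn-cn-cn-cn-cn-c
Petromyzon marinus	S1	p-g"-x-p	sn-n"-c-xn
Petromyzon marinus	S2	p-g"	sn-n"-c
Petromyzon marinus	S3	p-g"-x	sn-n"-c-x
Petromyzon marinus	S4	p-g"-x-ğ	sn-n"-c-xň-c
Ciona intestinalis	-	g-g-g-g-g-g-g	s-n-c-n-c-n-c-n-c-n-c-n-c-n-c
Caenorhabditis elegans	1	g-g-g	s-ncnc-n-c
Caenorhabditis elegans	2	G	(s)-(sn)-(n)c-t
Monosiga brevicollis	a	g-g-g-g-p	s-ncncncncn
Monosiga brevicollis	b	g-x	sn-cx-x-x-x
Dictyostelium discoideum	-	G	sn-c
Plant	-	x-ğ	sx-x-x-xňc-y
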