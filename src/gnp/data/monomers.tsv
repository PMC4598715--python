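# Monomer building blocks for scaffold assembly (synthetic reconstruction;
# user-extensible). `fragment` is the chainable N-to-C residue SMILES: amino
# acids read N...C(=O); fatty acyls read R-C(=O); ketide units are alpha
# carbon plus carbonyl. The free monomer is fragment+OH; monoisotopic masses
# are computed from that form at load time.
code	name	class	fragment
ala	alanine	amino_acid	NC(C)C(=O)
arg	arginine	amino_acid	NC(CCCNC(=N)N)C(=O)
asn	asparagine	amino_acid	NC(CC(N)=O)C(=O)
asp	aspartate	amino_acid	NC(CC(=O)O)C(=O)
cys	cysteine	amino_acid	NC(CS)C(=O)
gln	glutamine	amino_acid	NC(CCC(N)=O)C(=O)
glu	glutamate	amino_acid	NC(CCC(=O)O)C(=O)
gly	glycine	amino_acid	NCC(=O)
his	histidine	amino_acid	NC(Cc1c[nH]cn1)C(=O)
ile	isoleucine	amino_acid	NC(C(C)CC)C(=O)
leu	leucine	amino_acid	NC(CC(C)C)C(=O)
lys	lysine	amino_acid	NC(CCCCN)C(=O)
met	methionine	amino_acid	NC(CCSC)C(=O)
phe	phenylalanine	amino_acid	NC(Cc1ccccc1)C(=O)
pro	proline	amino_acid	N1CCCC1C(=O)
ser	serine	amino_acid	NC(CO)C(=O)
thr	threonine	amino_acid	NC(C(C)O)C(=O)
trp	tryptophan	amino_acid	NC(Cc1c[nH]c2ccccc12)C(=O)
tyr	tyrosine	amino_acid	NC(Cc1ccc(O)cc1)C(=O)
val	valine	amino_acid	NC(C(C)C)C(=O)
orn	ornithine	amino_acid	NC(CCCN)C(=O)
dab	diaminobutyrate	amino_acid	NC(CCN)C(=O)
hse	homoserine	amino_acid	NC(CCO)C(=O)
hasp	beta-hydroxyaspartate	amino_acid	NC(C(O)C(=O)O)C(=O)
clthr	4-chlorothreonine	amino_acid	NC(C(O)CCl)C(=O)
dhb	dehydrobutyrate	amino_acid	NC(=CC)C(=O)
mal	malonate	ketide_unit	CC(=O)
mmal	methylmalonate	ketide_unit	C(C)C(=O)
c8	octanoyl	fatty_acyl	CCCCCCCC(=O)
c9	nonanoyl	fatty_acyl	CCCCCCCCC(=O)
c10	decanoyl	fatty_acyl	CCCCCCCCCC(=O)
c11	undecanoyl	fatty_acyl	CCCCCCCCCCC(=O)
c12	dodecanoyl	fatty_acyl	CCCCCCCCCCCC(=O)
c13	tridecanoyl	fatty_acyl	CCCCCCCCCCCCC(=O)
c14	tetradecanoyl	fatty_acyl	CCCCCCCCCCCCCC(=O)
c15	pentadecanoyl	fatty_acyl	CCCCCCCCCCCCCCC(=O)
c16	hexadecanoyl	fatty_acyl	CCCCCCCCCCCCCCCC(=O)
c8-oh	3-hydroxyoctanoyl	fatty_acyl	CCCCCC(O)CC(=O)
c10-oh	3-hydroxydecanoyl	fatty_acyl	CCCCCCCC(O)CC(=O)
c12-oh	3-hydroxydodecanoyl	fatty_acyl	CCCCCCCCCC(O)CC(=O)
c13-oh	3-hydroxytridecanoyl	fatty_acyl	CCCCCCCCCCC(O)CC(=O)
c14-oh	3-hydroxytetradecanoyl	fatty_acyl	CCCCCCCCCCCC(O)CC(=O)
c15-oh	3-hydroxypentadecanoyl	fatty_acyl	CCCCCCCCCCCCC(O)CC(=O)
c16-oh	3-hydroxyhexadecanoyl	fatty_acyl	CCCCCCCCCCCCCC(O)CC(=O)
c12-2oh	3,4-dihydroxydodecanoyl	fatty_acyl	CCCCCCCCC(O)C(O)CC(=O)
c13-2oh	3,4-dihydroxytridecanoyl	fatty_acyl	CCCCCCCCCC(O)C(O)CC(=O)
c14-2oh	3,4-dihydroxytetradecanoyl	fatty_acyl	CCCCCCCCCCC(O)C(O)CC(=O)
c15-2oh	3,4-dihydroxypentadecanoyl	fatty_acyl	CCCCCCCCCCCC(O)C(O)CC(=O)
c16-2oh	3,4-dihydroxyhexadecanoyl	fatty_acyl	CCCCCCCCCCCCC(O)C(O)CC(=O)
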