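# Bundled PTM / phosphorylation site patterns in the package's PROSITE dialect.
# Columns: site class name <TAB> pattern <TAB> PROSITE accession.
# Each pattern was checked against the corresponding PROSITE entry.
N-glycosylation	N-{P}-[ST]-{P}	PS00001
cAMP/cGMP-kinase	[RK](2)-X-[ST]	PS00004
protein-kinase-C	[ST]-X-[RK]	PS00005
casein-kinase-II	[ST]-X(2)-[DE]	PS00006
tyrosine-kinase	[RK]-X(2,3)-[DE]-X(2,3)-Y	PS00007
N-myristoylation	G-{EDRKHPFYW}-X(2)-[STAGCN]-{P}	PS00008
amidation	X-G-[RK]-[RK]	PS00009
P-loop-ATP/GTP-A	[AG]-X(4)-G-K-[ST]	PS00017
leucine-zipper	L-X(6)-L-X(6)-L-X(6)-L	PS00029
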