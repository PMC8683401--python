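# The 29 BrCNGC family members of Brassica rapa L. (BRAD accessions) plus the
# discarded truncated accession Bra022235, transcribed from the published
# family summary table.  Coordinates are 1-based inclusive genomic positions.
# length_aa comes from the published protein-properties table for the 29
# members; the published record does not print a length for Bra022235 ("a
# short truncated sequence"), so its length here is a synthetic representative
# value below the 500 aa cutoff.  Bra022235 lacks the CNBD, hence no cNMP
# domain call.  at_ortholog = corresponding AtCNGC number.
gene	accession	chromosome	start	stop	strand	length_aa	primary_domains	secondary_domains	group	at_ortholog
BrCNGC1	Bra034281	A04	11980216	11982791	+	647	cNMP,IT	CaMBD,IQ	I	12
BrCNGC2	Bra003323	A07	15879616	15883454	-	666	cNMP,IT	IQ	I	12
BrCNGC3	Bra004537	A05	687357	690331	-	702	cNMP,IT	IQ	I	3
BrCNGC4	Bra031515	A01	16651616	16656087	+	556	cNMP,IT	IQ	I	3
BrCNGC5	Bra000937	A03	14054247	14058116	-	705	cNMP,IT	CaMBD,IQ	I	13
BrCNGC6	Bra003081	A10	5414086	5416746	-	758	cNMP,IT	CaMBD,IQ	I	1
BrCNGC7	Bra022632	A02	7390572	7393211	+	739	cNMP,IT	CaMBD,IQ	I	1
BrCNGC8	Bra026086	A06	5904523	5907153	-	712	cNMP,IT	CaMBD,IQ	II	7
BrCNGC9	Bra020402	A02	5537255	5540170	-	749	cNMP,IT	CaMBD,IQ	II	5
BrCNGC10	Bra032132	A04	11074762	11077889	-	746	cNMP,IT	CaMBD,IQ	II	6
BrCNGC11	Bra039221	A09	32929402	32932962	+	737	cNMP,IT	CaMBD,IQ	II	6
BrCNGC12	Bra024067	A03	27904482	27907069	-	712	cNMP,IT	CaMBD,IQ	II	9
BrCNGC13	Bra011963	A07	13141306	13144346	+	684	cNMP,IT	CaMBD,IQ	III	15
BrCNGC14	Bra008733	A10	12426314	12429518	+	714	cNMP,IT	CaMBD,IQ	III	18
BrCNGC15	Bra018089	A06	9846882	9849809	+	706	cNMP,IT	CaMBD,IQ	III	16
BrCNGC16	Bra011186	A01	3422819	3426535	+	728	cNMP,IT	CaMBD,IQ	III	17
BrCNGC17	Bra007839	A09	32710513	32713938	-	733	cNMP,IT	CaMBD,IQ	III	14
BrCNGC18	Bra032081	A04	11383157	11386389	+	728	cNMP,IT	CaMBD,IQ	III	14
BrCNGC19	Bra022702	A02	6903420	6907955	+	695	cNMP,IT	CaMBD,IQ	IV-a	4
BrCNGC20	Bra003001	A10	6203509	6208673	-	698	cNMP,IT	CaMBD,IQ	IV-a	4
BrCNGC21	Bra008699	A10	12252329	12255245	+	719	cNMP,IT	CaMBD,IQ	IV-a	2
BrCNGC22	Bra001678	A03	17843897	17852047	+	654	cNMP,IT		IV-b	20
BrCNGC23	Bra031529	A01	16542495	16546796	-	758	cNMP,IT		IV-b	20
BrCNGC24	Bra029958	A01	14741686	14746906	+	670	cNMP,IT	CaMBD,IQ	IV-b	20
BrCNGC25	Bra021265	A01	22108307	22111729	-	743	cNMP,IT	CaMBD,IQ	IV-b	19
BrCNGC26	Bra022233	A05	19633895	19637029	-	748	cNMP,IT	CaMBD,IQ	IV-b	19
BrCNGC27	Bra001676	A03	17833555	17836622	+	680	cNMP,IT		IV-b	20
BrCNGC28	Bra021266	A01	22102703	22106050	+	760	cNMP,IT	CaMBD,IQ	IV-b	20
BrCNGC29	Bra022232	A05	19638792	19642102	-	786	cNMP,IT	CaMBD,IQ	IV-b	19
	Bra022235					224	IT
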