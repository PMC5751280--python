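chrom	gene	pos	ref	alt	rsid	cdna	protein	consequence	cadd	maf_ctrl	maf_case	functional_assay
chr3	ITPR1	4714920	A	G	rs35789999	c.A2260G	p.M754V	nonsynonymous	15.92	0.0014		0
chr3	ITPR1	4716885	C	T	rs201519806	c.C2687T	p.A896V	nonsynonymous	12.80		0.0011	0
chr3	ITPR1	4774887	G	T		c.G5147T	p.G1716V	nonsynonymous	15.77		0.0014	0
chr3	ITPR1	4821291	G	T	rs373973399	c.G6160T	p.A2054S	nonsynonymous	20.2		0.0013	0
chr3	ITPR1	4842276	G	A	rs201144431	c.G6910A	p.A2304T	nonsynonymous	16.91	0.0015	0.001	0
chr17	GP1BA	4837662	T	C	rs201408072	c.T1763C	p.V588A	nonsynonymous	15.12	0.0013		0
chr3	RAF1	12641707	C	T	rs555034652	c.G934A	p.V312M	nonsynonymous	12.39		0.0017	0
chr1	PTAFR	28477192	T	C	rs138629813	c.A341G	p.N114S	nonsynonymous	20.8		0.0018	0
chr1	PTAFR	28477408	C	A		c.G125T	p.R42L	nonsynonymous	14.45	0.0015		0
chr17	ITGA2B	42453084	C	T	rs74988902	c.G2602A	p.V868M	nonsynonymous	13.50		0.0014	0
chr17	ITGA2B	42455791	G	A	rs200481952	c.C2033T	p.A678V	nonsynonymous	20.4		0.0015	0
chr17	ITGA2B	42457474	G	A	rs548977341	c.C1648T	p.R550W	nonsynonymous	22.3	0.0018		0
chr17	ITGA2B	42463054	G	C	rs76066357	c.C439G	p.L147V	nonsynonymous	11.09		0.0025	0
chr17	ITGB3	45363765	A	G	rs56173532	c.A754G	p.I252V	nonsynonymous	13.67	0.0012		0
chr17	ITGB3	45376796	G	A	rs144884023	c.G1813A	p.G605S	nonsynonymous	35		0.0013	0
chr19	PTGIR	47126849	G	A	rs4987262	c.C634T	p.R212C	nonsynonymous	22.3		0.0034	0
chr5	ITGA2	52344487	A	G	rs55973669	c.A517G	p.I173V	nonsynonymous	12.10		0.0022	0
chr19	GP6	55543660	G	A	rs199588110	c.C172T	p.R58C	nonsynonymous	18.28	0.0025	0.0016	0
chr19	GP6	55543660	G	A	rs199588110	c.C172T	p.R58C	nonsynonymous	18.28	0.0023		0
chr19	GP6	55543692	C	T	rs750889036	c.G140A	p.R47Q	nonsynonymous	10.75		0.0019	0
chr11	FERMT3	63974970	T	G	rs759179590	c.T134G	p.V45G	nonsynonymous	33	0.0035	0.0042	0
chr11	FERMT3	63974995	C	G	rs142815441	c.C159G	p.I53M	nonsynonymous	12.17	0.0013		0
chr11	FERMT3	63978538	G	A	rs762181713	c.G409A	p.E137K	nonsynonymous	29.0		0.0014	0
chr11	P2RY2	72945434	T	C	rs148391446	c.T230C	p.V77A	nonsynonymous	14.97		0.0017	0
chr11	P2RY2	72945799	A	G	rs141776297	c.A595G	p.S199G	nonsynonymous	15.02		0.0021	0
chr11	P2RY2	72945799	A	G	rs141776297	c.A595G	p.S199G	nonsynonymous	15.02	0.0019	0.0026	0
chr11	P2RY2	72946279	T	C	rs74472890	c.T1075C	p.S359P	nonsynonymous	12.54	0.0024		0
chr3	GP9	128781048	G	A	rs3796130	c.G466A	p.A156T	nonsynonymous	12.21	0.0015		0
chr3	P2RY12	151055962	C	A		c.G672T	p.R224S	nonsynonymous	15		0.0021	1
chr3	P2RY12	151056084	G	T		c.C550A	p.L184I	nonsynonymous	15.13		0.0013	1
chr3	P2RY1	152554155	G	A		c.G584A	p.R195H	nonsynonymous	18.35	0.0012	0.0034	1
chr3	P2RY1	152554326	C	A		c.C755A	p.S252Y	nonsynonymous	22.4		0.0015	1
chr3	P2RY1	152554395	C	A		c.C824A	p.P275H	nonsynonymous	22.8		0.0013	1
chr3	P2RY1	152554482	C	T	rs868057570	c.C911T	p.A304V	nonsynonymous	12.84		0.0026	1
chr1	PEAR1	156878116	C	T		c.C1099T	p.R367W	nonsynonymous	18.01		0.0012	0
chr1	SELP	169576246	G	A		c.C1460T	p.A487V	nonsynonymous	12.76	0.0017		0
chr1	SELP	169581608	G	A	rs139249907	c.C808T	p.R270X	stopgain	13.86		0.0016	0
chr3	GP5	194117640	C	A		c.G1372T	p.A458S	nonsynonymous	10.81		0.0012	0
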