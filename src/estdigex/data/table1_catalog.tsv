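set_id	slot	chrom	copies	code
IDG001	A	1A	1	-
IDG001	B	1B	1	-
IDG001	D	1D	1	-
IDG002	A	1A	1	-
IDG002	B	1B	1	-
IDG002	D	1D	1	-
IDG003	A	1A	1	-
IDG003	B	1B	1	-
IDG003	D	1D	1	-
IDG004	A	1A	1	-
IDG004	B	1B	1	-
IDG004	D	1D	1	-
IDG005	A	1A	1	-
IDG005	B	1B	1	-
IDG005	D	1D	1	-
IDG006	A	1A	1	-
IDG006	B	1B	1	-
IDG006	D	1D	1	-
IDG007	A	1A	1	-
IDG007	B	1B	1	-
IDG007	D	1D	1	-
IDG008	A	1A	1	-
IDG008	B	1B	1	-
IDG008	D	1D	1	-
IDG009	A	1A	1	-
IDG009	B	1B	1	-
IDG009	D	1D	1	-
IDG010	A	1A	1	-
IDG010	B	1B	1	-
IDG010	D	1D	1	-
IDG011	A	1A	1	-
IDG011	B	-	0	c
IDG011	D	-	0	a
IDG012	A	-	0	c
IDG012	B	1B	1	-
IDG012	D	1D	1	-
IDG013	A	-	0	b
IDG013	B	1B	1	-
IDG013	D	-	0	b
IDG014	A	2A	1	-
IDG014	B	2B	1	-
IDG014	D	2D	1	-
IDG015	A	2A	1	-
IDG015	B	-	0	a
IDG015	D	2D	1	-
IDG016	A	2A	1	-
IDG016	B	2B	1	-
IDG016	D	2D	1	-
IDG017	A	2A	1	-
IDG017	B	2B	1	-
IDG017	D	-	0	b
IDG018	A	-	0	a
IDG018	B	2B	1	-
IDG018	D	2D	1	-
IDG019	A	3A	1	-
IDG019	B	3B	1	-
IDG019	D	3D	1	-
IDG020	A	3A	1	-
IDG020	B	3B	1	-
IDG020	D	3D	1	-
IDG021	A	3A	1	-
IDG021	B	3B	1	-
IDG021	D	3D	1	-
IDG022	A	3A	1	-
IDG022	B	3B	1	-
IDG022	D	3D	1	-
IDG023	A	3A	1	-
IDG023	B	3B	1	-
IDG023	D	3D	1	-
IDG024	A	3A	1	-
IDG024	B	3B	1	-
IDG024	D	3D	1	-
IDG025	A	3A	1	-
IDG025	B	3B	1	-
IDG025	D	3D	1	-
IDG026	A	3A	1	-
IDG026	B	3B	1	-
IDG026	D	3D	1	-
IDG027	A	3A	1	-
IDG027	B	-	0	c
IDG027	D	3D	1	-
IDG022	A	3A	1	-
IDG022	B	3B	1	-
IDG022	D	3D	1	-
IDG029	A	3A	2	-
IDG029	B	3B	2	-
IDG029	D	3D	2	-
IDG030	A	3A	1	-
IDG030	B	3B	1	-
IDG030	D	3D	1	-
IDG031	A	-	0	c
IDG031	B	-	0	c
IDG031	D	3D	1	-
IDG032	A	4A	1	-
IDG032	B	-	0	b
IDG032	D	5D	1	-
IDG033	A	4A	1	-
IDG033	B	4B	1	-
IDG033	D	4D	1	-
IDG034	A	-	0	c
IDG034	B	4B	1	-
IDG034	D	4D	1	-
IDG035	A	5A	2	-
IDG035	B	4B	1	-
IDG035	D	4D	2	-
IDG036	A	5A	1	-
IDG036	B	5B	1	-
IDG036	D	5D	1	-
IDG037	A	5A	1	-
IDG037	B	5B	1	-
IDG037	D	5D	1	-
IDG038	A	5A	1	-
IDG038	B	5B	1	-
IDG038	D	5D	1	-
IDG039	A	5A	1	-
IDG039	B	5B	1	-
IDG039	D	5D	1	-
IDG040	A	-	0	c
IDG040	B	5B	2	-
IDG040	D	5D	1	-
IDG041	A	-	0	b
IDG041	B	5B	1	-
IDG041	D	5D	1	-
IDG042	A	6A	8	-
IDG042	B	6B	3	-
IDG042	D	6D	3	-
IDG043	A	-	0	b
IDG043	B	6B	1	-
IDG043	D	6D	2	-
IDG044	A	6A	1	-
IDG044	B	6B	1	-
IDG044	D	6D	1	-
IDG045	A	6A	1	-
IDG045	B	6B	1	-
IDG045	D	6D	1	-
IDG046	A	6A	1	-
IDG046	B	-	0	c
IDG046	D	-	0	b
IDG047	A	6A	1	-
IDG047	B	6B	1	-
IDG047	D	6D	1	-
IDG048	A	6A	1	-
IDG048	B	6B	1	-
IDG048	D	6D	1	-
IDG049	A	6A	2	-
IDG049	B	6B	1	-
IDG049	D	6D	1	-
IDG050.1	A	6A	1	-
IDG050.1	B	-	0	a
IDG050.1	D	6D	1	-
IDG050.2	A	6A	1	-
IDG050.2	B	-	0	b
IDG050.2	D	6D	1	-
IDG051	A	-	0	b
IDG051	B	6B	1	-
IDG051	D	6D	1	-
IDG052	A	-	0	c
IDG052	B	6B	2	-
IDG052	D	-	0	c
IDG053	A	-	0	a
IDG053	B	6B	1	-
IDG053	D	-	0	a
IDG054	A	7A	1	-
IDG054	B	7B	1	-
IDG054	D	7D	1	-
IDG055	A	7A	1	-
IDG055	B	7B	1	-
IDG055	D	7D	1	-
IDG056	A	7A	1	-
IDG056	B	7B	1	-
IDG056	D	7D	1	-
IDG057	A	7A	1	-
IDG057	B	-	0	a
IDG057	D	7D	1	-
IDG058	A	-	0	b
IDG058	B	7B	1	-
IDG058	D	-	0	b
IDG059	A	-	0	c
IDG059	B	-	0	c
IDG059	D	7D	1	-
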