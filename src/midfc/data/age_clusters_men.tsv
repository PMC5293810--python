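seed	volume_mm3	peak_z	x	y	z	side	label
VTA	3510	5.29	-33	-7	-29	L	Superior temporal gyrus/PHG
VTA	4077	4.84	27	11	-38	R	Superior temporal gyrus/PHG
VTA	1890	3.96	-21	-55	-23	L	Cerebellum
SNc	1620	5.60	9	-61	43	L/R	Precuneus/Superior parietal gyrus
SNc	4239	4.87	51	-49	49	R	Intraparietal sulcus
SNc	1485	4.55	42	-70	43	R	Angular gyrus
SNc	1539	4.52	-21	-34	-41	L	Cerebellum
SNc	1350	4.34	42	-43	-44	R	Cerebellum
SNc	2052	4.13	-24	-67	-47	R	Cerebellum
SNc	1053	3.91	-33	-52	-23	L	Cerebellum
SNc	1053	4.39	-38	-91	34	L	Superior parietal gyrus
SNc	1404	4.20	-33	-25	70	L	Precentral/Postcentral gyrus
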