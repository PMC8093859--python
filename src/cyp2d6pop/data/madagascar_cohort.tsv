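sample_id	haplotype_1	haplotype_2
MD001	*1	*2x2
MD002	*1	*35x2
MD003	*1	*10
MD004	*1	*10
MD005	*1	*10
MD006	*1	*10
MD007	*1	*10
MD008	*1	*10
MD009	*1	*10
MD010	*1	*10
MD011	*1	*10
MD012	*1	*10
MD013	*1	*10
MD014	*1	*10
MD015	*1	*10
MD016	*1	*10
MD017	*1	*10
MD018	*1	*10
MD019	*1	*10
MD020	*1	*10
MD021	*1	*10
MD022	*1	*10
MD023	*1	*10
MD024	*1	*10
MD025	*1	*10
MD026	*1	*10
MD027	*1	*10
MD028	*1	*10
MD029	*1	*10
MD030	*1	*10
MD031	*1	*10
MD032	*1	*10
MD033	*1	*36+*10
MD034	*1	*36+*10
MD035	*1	*36+*10
MD036	*1	*36+*10
MD037	*1	*36+*10
MD038	*1	*36+*10
MD039	*1	*36+*10
MD040	*1	*36+*10
MD041	*1	*36+*10
MD042	*1	*36+*10
MD043	*1	*36+*10
MD044	*1	*36+*10
MD045	*1	*36+*10
MD046	*1	*36+*10
MD047	*1	*36+*10
MD048	*1	*36+*10
MD049	*1	*36+*10
MD050	*1	*36+*10
MD051	*1	*36+*10
MD052	*1	*36x2+*10
MD053	*2	*10
MD054	*2	*10
MD055	*2	*10
MD056	*2	*10
MD057	*2	*36+*10
MD058	*2	*36+*10
MD059	*36+*10	*45
MD060	*1	*17
MD061	*1	*17
MD062	*1	*17
MD063	*1	*17
MD064	*1	*17
MD065	*1	*17
MD066	*1	*17
MD067	*1	*17
MD068	*1	*17
MD069	*1	*17
MD070	*1	*17
MD071	*1	*17
MD072	*1	*17
MD073	*1	*17
MD074	*1	*17
MD075	*1	*17
MD076	*1	*17
MD077	*1	*17
MD078	*1	*17
MD079	*1	*17
MD080	*1	*17
MD081	*1	*29
MD082	*1	*29
MD083	*1	*29
MD084	*1	*29
MD085	*1	*29
MD086	*1	*29
MD087	*1	*29
MD088	*1	*29
MD089	*1	*29
MD090	*1	*29
MD091	*1	*29
MD092	*1	*29
MD093	*1	*41
MD094	*1	*41
MD095	*1	*41
MD096	*1	*41
MD097	*2	*17
MD098	*2	*17
MD099	*2	*17
MD100	*2	*29
MD101	*2	*29
MD102	*2	*29
MD103	*2	*41
MD104	*1	*1
MD105	*1	*1
MD106	*1	*1
MD107	*1	*1
MD108	*1	*1
MD109	*1	*1
MD110	*1	*1
MD111	*1	*1
MD112	*1	*1
MD113	*1	*1
MD114	*1	*1
MD115	*1	*1
MD116	*1	*1
MD117	*1	*1
MD118	*1	*1
MD119	*1	*1
MD120	*1	*1
MD121	*1	*1
MD122	*1	*2
MD123	*1	*2
MD124	*1	*2
MD125	*1	*2
MD126	*1	*2
MD127	*1	*2
MD128	*1	*2
MD129	*1	*2
MD130	*1	*2
MD131	*1	*2
MD132	*1	*2
MD133	*1	*2
MD134	*1	*2
MD135	*1	*45
MD136	*2	*45
MD137	*2x2	*5
MD138	*1x2	*10
MD139	*4	*36+*10
MD140	*4	*36+*10
MD141	*4x2	*36+*10
MD142	*5	*10
MD143	*5	*10
MD144	*5	*10
MD145	*10	*40
MD146	*36+*10	*100
MD147	*4	*29
MD148	*4	*29
MD149	*4x2	*41
MD150	*10	*10
MD151	*10	*10
MD152	*10	*10
MD153	*10	*10
MD154	*10	*10
MD155	*10	*10
MD156	*10	*10
MD157	*10	*36+*10
MD158	*10	*36+*10
MD159	*10	*36+*10
MD160	*10	*36+*10
MD161	*10	*36+*10
MD162	*10	*36+*10
MD163	*36+*10	*36+*10
MD164	*36+*10	*36+*10
MD165	*36+*10	*36+*10
MD166	*10	*17
MD167	*10	*17
MD168	*10	*17
MD169	*10	*17
MD170	*10	*17
MD171	*10	*29
MD172	*10	*29
MD173	*10	*29
MD174	*10	*29
MD175	*10	*29
MD176	*10	*29
MD177	*10	*41
MD178	*10	*41
MD179	*17	*36+*10
MD180	*17	*36+*10
MD181	*17	*36+*10
MD182	*17	*36+*10
MD183	*17	*36+*10
MD184	*17	*36+*10
MD185	*17	*36+*10
MD186	*36+*10	*41
MD187	*36+*10	*41
MD188	*36+*10	*41
MD189	*36+*10	*41
MD190	*36+*10	*41
MD191	*36+*10	*41
MD192	*1	*4
MD193	*1	*4
MD194	*1	*4
MD195	*1	*4
MD196	*1	*4
MD197	*1	*4x2
MD198	*1	*4x2
MD199	*1	*4x2
MD200	*1	*4x2
MD201	*1	*5
MD202	*1	*5
MD203	*1	*5
MD204	*17	*17
MD205	*17	*17
MD206	*17	*29
MD207	*17	*29
MD208	*17	*29
MD209	*17	*29
MD210	*17	*29
MD211	*17	*41
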