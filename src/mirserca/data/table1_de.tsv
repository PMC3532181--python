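mirna	log2_ratio	log2_ratio_prev	predicted	family	cluster_note
let-7b	0.04	-0.32	Yes	let-7	22: let-7a-3, miR-4763; intronic
let-7c	-0.87	-0.88	Yes	let-7	21: miR-99a; intronic
let-7d	-1.34	-1.33	Yes	let-7	9: let-7a-1, let-7f-1; intronic
let-7g	-1.50	-1.67	Yes	let-7	3: as single gene; intronic
miR-1	-3.28	-1.89	No	miR-1	18: miR-133a-1; intronic | 20: miR-133a-2; intronic
miR-122	3.28	ND	No	miR-122	18: miR-3591; intergenic
miR-125a-5p	-1.53	-1.46	No	miR-125	19: let-7e, miR-99b; intronic
miR-125b	-0.44	-0.47	No	miR-125	11: as single gene; intronic
miR-126	-2.00	-0.50	No	miR-126	9: as single gene; intronic
miR-133a	-1.52	ND	No	miR-133	18: miR-1-2; intronic | 20: miR-1-1; intronic
miR-133b	-1.53	ND	No	miR-133	6: miR-206; intronic
miR-140-3p	0.32	ND	No	miR-140	16: as single gene; intronic
miR-143	-0.26	ND	No	miR-143	5: miR-145; intergenic
miR-145	-0.79	ND	No	miR-145	5: miR-143; intergenic
miR-150	-1.63	-1.60	No	miR-150	19: as single gene; intergenic
miR-16	-0.03	ND	No	miR-15	13: miR-15a; intronic | 3: miR-15a; intronic
miR-195	-0.51	-1.37	Yes	miR-15	17: miR-497; intronic
miR-197	-0.57	ND	No	miR-197	1: as single gene; intergenic
miR-199a-3p	0.39	ND	No	miR-199	19: as single gene; intronic | 1: miR-199a-2, miR-3120, miR-214; intronic
miR-19b	-2.36	ND	Yes	miR-19	13: miR-17, miR-18a, miR-19a, miR-20a, miR-92a-1; intergenic | X: miR-106a, miR-18b, miR-20b, miR-92a-2, miR-363; intergenic
miR-21	-0.05	ND	No	miR-21	17: as single gene; intergenic
miR-23a	-1.71	-0.20	No	miR-23	19: miR-27a, miR-24-2; intergenic
miR-26a	-1.50	-0.54	No	miR-26	3: as single gene; intronic | 12: as single gene; intronic
miR-27a	-1.97	-1.60	No	miR-27	19: miR-23a, miR-24-2; intergenic
miR-27b	-2.18	-1.19	No	miR-27	9: miR-23b, miR-24-1, miR-3074; intronic
miR-29a	-1.40	ND	Yes	miR-29	7: miR-29b-1; intergenic
miR-29c	-2.28	ND	No	miR-29	1: miR-29b-2; intergenic
miR-30a	-2.23	-1.25	Yes	miR-30	6: as single gene; intronic
miR-30b	-3.03	-2.01	Yes	miR-30	8: miR-30d; intergenic
miR-30c	-2.70	-2.08	Yes	miR-30	1: miR-30e; intronic | 6: as single gene; intronic
miR-30d	-1.31	ND	Yes	miR-30	8: miR-30b; intergenic
miR-30e	-2.71	ND	Yes	miR-30	1: miR-30c-1; intronic
miR-320a	2.37	0.98	No	miR-320	8: as single gene; intergenic
miR-320b	2.24	0.98	No	miR-320	1: two copies as single gene; one intronic and one intergenic
miR-320c	2.27	0.98	No	miR-320	18: two copies as single gene; intronic
miR-320d	2.13	0.98	No	miR-320	13: as single gene; intergenic | X: as single gene; intergenic
miR-378	-1.66	ND	No	miR-378	5: as single gene; intronic
miR-483-5p	2.92	ND	No	miR-483	11: as single gene; intronic
miR-499-5p	-2.94	-3.36	Yes	miR-499	20: miR-499a; intronic
miR-574-3p	2.25	2.46	Yes	miR-574	4: as single gene; intronic
miR-574-5p	2.17	3.18	No	miR-574
miR-98	-1.76	-3.10	Yes	let-7	X: let-7f; intronic
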