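mirna	dG_bind	dG_flank3	dG_flank5	position	seed
miR-122	-24.9	-9.9	-8.7	313-334	no
miR-122	-23.7	-3.0	-8.2	788-809	no
miR-122	-21.5	-0.2	-9.5	496-517	no
miR-122	-19.3	-8.2	-7.5	253-274	no
miR-122	-19.3	-3.5	-5.2	476-497	no
miR-122	-19.3	-6.3	-9.0	458-479	no
miR-122	-18.1	-4.3	-8.3	151-172	no
miR-199a-3p	-22.0	-4.9	-9.5	380-401	yes
miR-199a-3p	-21.0	-3.1	-11.1	487-508	yes
miR-199a-3p	-18.6	-8.3	-3.9	59-80	yes
miR-199a-3p	-18.1	-7.5	-8.3	251-272	no
miR-320a	-21.2	-9.9	-9.3	405-426	no
miR-320a	-21.8	-9.0	0.3	798-819	no
miR-320a	-21.2	-4.7	-9.8	65-86	partially (1-4)
miR-320a	-23.7	-8.2	-8.2	687-708	no
miR-320a	-21.8	-9.1	-11.9	123-144	partially (1-6)
miR-320b	-21.2	-9.9	-9.3	405-426	no
miR-320b	-21.8	-9.0	0.3	798-819	no
miR-320b	-21.2	-4.7	-9.8	65-86	partially (1-4)
miR-320b	-23.7	-8.2	-8.2	687-708	no
miR-320b	-21.8	-9.1	-11.9	123-144	partially (1-6)
miR-320c	-19.1	-8.0	0.3	800-819	no
miR-320c	-24.0	-12.4	-8.2	689-708	no
miR-320c	-21.1	-11.4	-9.2	650-669	no
miR-320d	-23.4	-13.2	-8.2	690-708	no
miR-320d	-24.3	-12.2	-9.0	709-727	partially (1-4, 6-7)
miR-483-5p	-23.8	-13.1	-9.0	705-726	no
miR-483-5p	-21.8	-4.7	-8.5	63-84	no
miR-483-5p	-22.7	-9.1	-9.3	121-142	no
miR-483-5p	-20.3	-8.2	-3.0	789-810	Partially (1, 3-6, 8)
miR-574-3p	-22.9	-8.2	-6.5	347-368	No
miR-574-3p	-21.2	-2.7	-11.3	96-117	no
miR-574-5p	-21.7	-8.6	-8.0	263-285	No
miR-574-5p	-23.4	-4.9	-3.5	479-501	No
miR-574-5p	-18.2	-3.3	-3.5	12-34	No
miR-574-5p	-20.5	-9.0	0.3	797-819	Partially (1-5, 7)
miR-140-3p	-19.9	-8.2	-6.5	348-368	yes
miR-140-3p	-20.5	-9.9	-3.5	484-504	No
miR-140-3p	-19.7	-8.7	0.3	799-819	no
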